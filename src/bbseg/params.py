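"""Run parameters: a flat key=value text file a user can edit without code.

The dialect is deliberately minimal: one ``key=value`` per line, ``#`` starts
a comment, keys are case-insensitive, values are typed by the parameter's
declared type.  ``serialize`` then ``parse`` is the identity for every valid
parameter set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


class ParamError(ValueError):
    """A parameter file or value is invalid; the message names the key."""


@dataclass(frozen=True)
class ParamSet:
    """Everything that controls training, inference and assembly.

    Attributes
    ----------
    scales:
        Integer context-window magnifications. For scale ``s`` the network
        sees the ``patch_side*s`` square window around each pixel reduced to
        ``patch_side`` by block averaging.
    patch_side:
        Side (px, odd) of every down-sampled context window.
    dist_cap:
        Cap ``d_max`` (px) on the distance-to-region-edge regression target.
    fraction:
        Fraction F in (0, 1] of eligible training pixels actually drawn.
    epochs:
        Number of passes E over the drawn pixels; total presentations
        T = round(E * F * M) for M eligible pixels.
    balance_classes:
        Draw inside ("innie") and outside ("outie") pixels in equal number,
        oversampling the minority class with replacement.
    augment:
        Apply a random symmetry of the square (rotation/flip) to each
        training patch stack.
    learning_rate:
        Adam step size.
    batch_size:
        Samples per optimizer update.
    prob_threshold:
        Classification probability at or above which a pixel is foreground.
    marker_level:
        Predicted-distance level whose plateaus seed the watershed; negative
        means automatic (dist_cap - 2).
    min_region_px:
        Segments smaller than this many pixels are discarded.
    rgb_mode:
        "luma" collapses color input to a single channel; "keep3" feeds each
        color channel as separate stack channels.
    seg_strict_half:
        Use a strict > 1/2 overlap rule in the SEG score instead of >= 1/2.
    """

    scales: tuple[int, ...] = (1, 3, 9, 27)
    patch_side: int = 25
    dist_cap: int = 10
    fraction: float = 1.0
    epochs: int = 2
    balance_classes: bool = True
    augment: bool = True
    learning_rate: float = 0.001
    batch_size: int = 64
    prob_threshold: float = 0.5
    marker_level: float = -1.0
    min_region_px: int = 10
    seed: int = 0
    rgb_mode: str = "luma"
    seg_strict_half: bool = False
    save_prob_map: bool = False
    save_dist_map: bool = False
    save_binary: bool = False

    def __post_init__(self) -> None:
        if not self.scales or any(
            (not isinstance(s, int)) or s < 1 for s in self.scales
        ):
            raise ParamError("scales: must be a non-empty list of integers >= 1")
        if self.patch_side < 1 or self.patch_side % 2 == 0:
            raise ParamError("patch_side: must be a positive odd integer")
        if self.dist_cap < 1:
            raise ParamError("dist_cap: must be a positive integer")
        if not (0.0 < self.fraction <= 1.0):
            raise ParamError("fraction: must lie in (0, 1]")
        if self.epochs < 1:
            raise ParamError("epochs: must be a positive integer")
        if self.learning_rate <= 0:
            raise ParamError("learning_rate: must be positive")
        if self.batch_size < 1:
            raise ParamError("batch_size: must be a positive integer")
        if not (0.0 < self.prob_threshold < 1.0):
            raise ParamError("prob_threshold: must lie in (0, 1)")
        if self.min_region_px < 0:
            raise ParamError("min_region_px: must be non-negative")
        if self.rgb_mode not in ("luma", "keep3"):
            raise ParamError("rgb_mode: must be 'luma' or 'keep3'")

    @property
    def effective_marker_level(self) -> float:
        """Watershed seeding level; defaults to two pixels below the cap."""
        if self.marker_level < 0:
            return float(self.dist_cap - 2)
        return self.marker_level

    def replace(self, **kw) -> "ParamSet":
        return dataclasses.replace(self, **kw)


_BOOL_KEYS = {
    "balance_classes",
    "augment",
    "seg_strict_half",
    "save_prob_map",
    "save_dist_map",
    "save_binary",
}
_INT_KEYS = {"patch_side", "dist_cap", "epochs", "batch_size", "min_region_px", "seed"}
_FLOAT_KEYS = {"fraction", "learning_rate", "prob_threshold", "marker_level"}
_STR_KEYS = {"rgb_mode"}


def _format_value(key: str, value) -> str:
    if key == "scales":
        return ",".join(str(s) for s in value)
    if key in _BOOL_KEYS:
        return "true" if value else "false"
    return repr(value) if isinstance(value, float) else str(value)


def _parse_value(key: str, raw: str):
    try:
        if key == "scales":
            return tuple(int(tok) for tok in raw.replace(" ", "").split(",") if tok)
        if key in _BOOL_KEYS:
            low = raw.lower()
            if low in ("true", "1", "yes", "on"):
                return True
            if low in ("false", "0", "no", "off"):
                return False
            raise ValueError(raw)
        if key in _INT_KEYS:
            return int(raw)
        if key in _FLOAT_KEYS:
            return float(raw)
        return raw
    except ValueError as exc:
        raise ParamError(f"{key}: cannot parse value {raw!r}") from exc


def serialize_params(params: ParamSet) -> str:
    """Render a ParamSet as the editable key=value text dialect."""
    lines = ["# bbseg parameters: key=value, '#' starts a comment"]
    for f in dataclasses.fields(params):
        lines.append(f"{f.name}={_format_value(f.name, getattr(params, f.name))}")
    return "\n".join(lines) + "\n"


def parse_params(text: str) -> ParamSet:
    """Parse the key=value dialect, filling omitted keys with defaults.

    Unknown keys and out-of-range values raise :class:`ParamError` naming
    the offending key.
    """
    known = {f.name for f in dataclasses.fields(ParamSet)}
    overrides = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ParamError(f"line {lineno}: expected key=value, got {stripped!r}")
        key, _, raw = stripped.partition("=")
        key = key.strip().lower()
        if key not in known:
            raise ParamError(f"{key}: unknown parameter")
        overrides[key] = _parse_value(key, raw.strip())
    return ParamSet(**overrides)


def load_params(path: str | Path) -> ParamSet:
    """Read and validate a parameter file."""
    return parse_params(Path(path).read_text())


def save_params(params: ParamSet, path: str | Path) -> None:
    Path(path).write_text(serialize_params(params))
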