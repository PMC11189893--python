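"""High-level train / predict / evaluate workflows over a project folder."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, inference, sampling, synthetic, training
from .io import (
    read_aoi_raster,
    read_label_raster,
    read_raster,
    write_float_raster,
    write_label_raster,
)
from .labels import default_aoi
from .network import DualHeadCNN, NetworkSpec
from .params import ParamSet
from .project import ProjectLayout, open_project


def train_project(root) -> tuple[DualHeadCNN, training.TrainLog]:
    """Train a network on a project's training images and save it."""
    layout = open_project(root)
    params = layout.params()
    images, masks, aois = layout.load_training_set()
    net, log = train_on_arrays(images, masks, aois, params)
    net.save(
        layout.model_path,
        provenance={"seed": params.seed, "T": log.steps},
    )
    log.to_frame().to_csv(layout.dir("outputs") / "train_log.csv", index=False)
    return net, log


def train_on_arrays(images, masks, aois, params: ParamSet):
    """Library-level training: images + label maps (+AOIs) -> trained net."""
    norm = [sampling.normalize_image(img, params.rgb_mode) for img in images]
    aois = [
        a if a is not None else default_aoi(m.shape) for a, m in zip(aois, masks)
    ]
    rng = np.random.default_rng(params.seed)
    draw, _budget = sampling.draw_samples(norm, masks, aois, params, rng)
    n_ch = draw.extractors[0].n_channels
    net = DualHeadCNN(
        NetworkSpec(patch_side=params.patch_side, n_channels=n_ch),
        seed=params.seed,
    )
    log = training.fit(net, draw, params, rng)
    return net, log


def predict_project(root) -> list[Path]:
    """Segment every test image; write labeled rasters (+optional maps)."""
    layout = open_project(root)
    params = layout.params()
    if not layout.model_path.exists():
        raise FileNotFoundError("no trained model; run train first")
    net = DualHeadCNN.load(layout.model_path)
    written = []
    outdir = layout.dir("outputs")
    for path in layout.test_images():
        image = read_raster(path)
        aoi_path = layout.aoi_for(path)
        aoi = read_aoi_raster(aoi_path) if aoi_path else None
        seg, pmap, dmap = inference.segment_image(net, image, aoi, params)
        seg_path = outdir / f"{path.stem}_seg.tif"
        write_label_raster(seg.labels, seg_path)
        inference.region_table(seg).to_csv(
            outdir / f"{path.stem}_regions.csv", index=False
        )
        if params.save_prob_map:
            write_float_raster(pmap, outdir / f"{path.stem}_prob.tif")
        if params.save_dist_map:
            write_float_raster(dmap, outdir / f"{path.stem}_dist.tif")
        if params.save_binary:
            write_label_raster(
                (pmap >= params.prob_threshold).astype(np.uint16),
                outdir / f"{path.stem}_binary.tif",
            )
        written.append(seg_path)
    return written


def evaluate_project(root, truth_subdir: str = "test_masks") -> pd.DataFrame:
    """Score saved segmentations against ground-truth masks.

    Returns the per-image table; writes per-region and aggregate CSVs.
    The dataset SEG pools all true regions across images.
    """
    layout = open_project(root)
    params = layout.params()
    outdir = layout.dir("outputs")
    results, rows, region_frames = [], [], []
    for path in layout.test_images():
        seg_path = outdir / f"{path.stem}_seg.tif"
        if not seg_path.exists():
            raise FileNotFoundError(f"{seg_path.name} missing; run predict first")
        truth_dir = layout.dir(truth_subdir)
        truth_path = None
        for suffix in (".png", ".tif", ".tiff"):
            cand = truth_dir / (path.stem + suffix)
            if cand.exists():
                truth_path = cand
                break
        if truth_path is None:
            raise FileNotFoundError(f"no truth mask for {path.name} in {truth_subdir}/")
        truth = read_label_raster(truth_path)
        pred = read_label_raster(seg_path)
        aoi_path = layout.aoi_for(path)
        aoi = read_aoi_raster(aoi_path) if aoi_path else None
        res = evaluation.seg_score(truth, pred, aoi, strict_half=params.seg_strict_half)
        results.append(res)
        frame = res.rows.copy()
        frame.insert(0, "image", path.stem)
        region_frames.append(frame)
        rows.append({"image": path.stem, "n_true": len(res.rows), "seg": res.seg})
    per_image = pd.DataFrame(rows)
    pooled = evaluation.pooled_seg(results)
    pd.concat(region_frames, ignore_index=True).to_csv(
        outdir / "eval_regions.csv", index=False
    )
    summary = per_image.copy()
    summary.loc[len(summary)] = {
        "image": "__pooled__",
        "n_true": int(sum(len(r.rows) for r in results)),
        "seg": pooled,
    }
    summary.to_csv(outdir / "eval_summary.csv", index=False)
    return summary


def write_fixture_project(
    root,
    preset: str = "disks",
    seed: int = 0,
    n_train: int = 1,
    n_test: int = 1,
    scene: synthetic.SceneSpec | None = None,
) -> ProjectLayout:
    """Create a ready-to-train project filled with synthetic scenes."""
    from .project import create_project

    layout = create_project(root)
    rng = np.random.default_rng(seed)
    if preset == "disks":
        spec = scene or synthetic.SceneSpec()
        for i in range(n_train):
            img, lab = synthetic.make_disks(spec, rng)
            write_label_raster(
                img.pixels, layout.dir("train_images") / f"scene{i}.png"
            )
            write_label_raster(lab, layout.dir("train_masks") / f"scene{i}.png")
        (layout.root / "test_masks").mkdir(exist_ok=True)
        for i in range(n_test):
            img, lab = synthetic.make_disks(spec, rng)
            write_label_raster(
                img.pixels, layout.dir("test_images") / f"test{i}.png"
            )
            write_label_raster(lab, layout.root / "test_masks" / f"test{i}.png")
    elif preset == "lattice":
        spec_l = synthetic.LatticeSpec(deletion_rate=0.15)
        for i in range(n_train):
            img, mask = synthetic.make_lattice(spec_l, rng)
            write_label_raster(
                img.pixels, layout.dir("train_images") / f"lattice{i}.png"
            )
            write_label_raster(
                mask.astype(np.uint16), layout.dir("train_masks") / f"lattice{i}.png"
            )
        (layout.root / "test_masks").mkdir(exist_ok=True)
        for i in range(n_test):
            img, mask = synthetic.make_lattice(spec_l, rng)
            write_label_raster(
                img.pixels, layout.dir("test_images") / f"latticetest{i}.png"
            )
            write_label_raster(
                mask.astype(np.uint16), layout.root / "test_masks" / f"latticetest{i}.png"
            )
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return layout
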