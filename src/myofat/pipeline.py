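"""End-to-end segmentation pipeline: clustering → cleanup → snakes →
compartments → per-slice fat fractions → middle-slice aggregation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .active_contour import Contour, fit_limb_and_muscle_contours
from .compartments import (
    CompartmentMasks,
    FatFractionResult,
    aggregate_fraction,
    detect_bone,
    fat_fraction,
    flag_failure,
    partition_compartments,
)
from .config import PipelineConfig
from .errors import MyofatError, SegmentationFailure
from .io import ImageVolume, contours_to_frame, write_labels

log = logging.getLogger("myofat")


@dataclass
class SliceResult:
    fraction: float | None
    flags: list[str]
    masks: CompartmentMasks | None = None
    limb: Contour | None = None
    muscle: Contour | None = None


@dataclass
class PipelineResult:
    result: FatFractionResult
    slices: list[SliceResult] = field(default_factory=list)

    @property
    def needs_manual_correction(self) -> bool:
        return any(s.flags for s in self.slices)


def segment_slice(image: np.ndarray, config: PipelineConfig) -> SliceResult:
    """Run the full per-slice chain on one axial image."""
    from .tissue_clustering import classify_slice

    raw, cleaned, _ = classify_slice(
        image,
        n_restarts=config.kmeans_restarts,
        seed=config.seed,
        closing_radius_px=config.closing_radius_px,
    )
    try:
        limb, muscle = fit_limb_and_muscle_contours(
            cleaned, config.snake_config(),
            support_closing_px=config.closing_radius_px,
            raw_tmap=raw,
        )
    except SegmentationFailure as exc:
        return SliceResult(None, [str(exc)])
    bone = detect_bone(image, raw, muscle)
    masks = partition_compartments(raw, limb, muscle, bone)
    flagged, reasons = flag_failure(
        masks,
        raw,
        min_fascia_fraction=config.min_fascia_fraction,
        boundary_support_radius_px=config.boundary_support_radius_px,
    )
    try:
        frac = fat_fraction(masks)
    except MyofatError as exc:
        return SliceResult(None, reasons + [str(exc)], masks, limb, muscle)
    return SliceResult(frac, reasons if flagged else [], masks, limb, muscle)


def segment_volume(volume: ImageVolume | np.ndarray,
                   config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Segment every slice and aggregate the fat fraction over the middle
    slices (slices with failure flags are excluded from the aggregate)."""
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    if data.ndim == 2:
        data = data[None]
    slices: list[SliceResult] = []
    for i in range(data.shape[0]):
        t0 = time.perf_counter()
        sr = segment_slice(data[i], config)
        log.info(
            "slice %d: fraction=%s flags=%s (%.2fs)",
            i, f"{sr.fraction:.4f}" if sr.fraction is not None else "n/a",
            sr.flags or "-", time.perf_counter() - t0,
        )
        slices.append(sr)
    per_slice = FatFractionResult(
        per_slice_fraction=[s.fraction if s.fraction is not None else np.nan
                            for s in slices],
        failure_flags=[s.flags if s.fraction is not None else
                       (s.flags or ["segmentation failed"]) for s in slices],
    )
    try:
        agg = aggregate_fraction(per_slice, n_middle=config.n_middle)
    except MyofatError as exc:
        # every slice flagged: no automatic aggregate, route to manual
        agg = FatFractionResult(
            per_slice_fraction=per_slice.per_slice_fraction,
            aggregate_fraction=None,
            failure_flags=per_slice.failure_flags,
            warnings=[str(exc)],
        )
    return PipelineResult(result=agg, slices=slices)


def run_pipeline(config: PipelineConfig, input_path: str | Path,
                 force: bool = False) -> PipelineResult:
    """File-to-files entry point: read a volume, segment it, write label
    maps, contours, the results CSV and a JSON run manifest."""
    from .io import read_volume

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_csv = out / "fractions.csv"
    if results_csv.exists() and not force:
        raise FileExistsError(
            f"{results_csv} exists; pass force=True / --force to overwrite"
        )
    vol = read_volume(input_path)
    res = segment_volume(vol, config)

    rows = [
        {"slice_index": i, "fraction": s.fraction,
         "flags": ";".join(s.flags), "source": "automatic"}
        for i, s in enumerate(res.slices)
    ]
    pd.DataFrame(rows).to_csv(results_csv, index=False)

    labels = np.stack(
        [s.masks.labels if s.masks is not None
         else np.zeros(vol.data.shape[1:], dtype=np.int16) for s in res.slices]
    )
    write_labels(labels, out / "compartments.nii.gz", vol.spacing_mm)
    contours = {
        i: {"limb": s.limb, "muscle": s.muscle}
        for i, s in enumerate(res.slices)
        if s.limb is not None and s.muscle is not None
    }
    contours_to_frame(contours).to_csv(out / "contours.csv", index=False)

    manifest = {
        "version": __version__,
        "input": str(input_path),
        "config": dataclasses.asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "aggregate_fraction": res.result.aggregate_fraction,
        "slices_used": res.result.slices_used,
        "failure_flags": res.result.failure_flags,
        "warnings": res.result.warnings,
        "needs_manual_correction": res.needs_manual_correction,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return res
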