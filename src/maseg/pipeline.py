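"""End-to-end orchestration of the three-step segmentation model.

    raw frame -> preprocess -> matched-filter response -> GA threshold
              -> coarse candidate mask -> area + roundness filter
              -> final microaneurysm mask [-> metrics vs. reference mask]

``run_on_array`` is the in-memory core; ``run_single`` and ``run_batch``
add file I/O, per-region CSV audit tables and JSON run records. The
``skip_fine`` flag stops after the coarse mask (the matched-filter-only
ablation); the coarse mask is always a superset of the final mask.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .ga_threshold import GAConfig, coarse_segment, rescale_u8
from .matched_filter import MFParams, build_bank, mf_response
from .metrics import batch_report, evaluate
from .morph_filter import FilterParams, fine_segment, label_regions, region_table
from .preprocess import PreprocessConfig, preprocess_image
from . import io as mio

__all__ = [
    "PipelineConfig",
    "SegmentationResult",
    "RunRecord",
    "run_on_array",
    "run_single",
    "run_batch",
    "config_to_yaml",
    "config_from_yaml",
]


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    matched_filter: MFParams = field(default_factory=MFParams)
    ga: GAConfig = field(default_factory=GAConfig)
    morph: FilterParams = field(default_factory=FilterParams)
    skip_fine: bool = False
    debug: bool = False
    seed: int | None = None  # overrides ga.rng_seed when set

    def resolved(self) -> "PipelineConfig":
        if self.seed is not None:
            self.ga.rng_seed = int(self.seed)
        return self

    def snapshot(self) -> dict:
        d = asdict(self)
        # tuples are not YAML/JSON-native
        mf = d["matched_filter"]
        if isinstance(mf.get("scale"), tuple):
            mf["scale"] = list(mf["scale"])
        return d


@dataclass
class SegmentationResult:
    enhanced: np.ndarray
    response: np.ndarray
    coarse_mask: np.ndarray
    fine_mask: np.ndarray
    threshold: int
    fitness: float
    regions: list

    @property
    def final_mask(self) -> np.ndarray:
        return self.fine_mask


@dataclass
class RunRecord:
    input_path: str
    config: dict
    threshold: int
    fitness: float
    n_regions_coarse: int
    n_regions_final: int
    metrics: dict | None
    timings_s: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def run_on_array(
    image: np.ndarray, config: PipelineConfig | None = None
) -> SegmentationResult:
    """Run all stages on an in-memory grayscale frame."""
    cfg = (config or PipelineConfig()).resolved()
    enhanced = preprocess_image(np.asarray(image, dtype=float), cfg.preprocess)
    bank = build_bank(cfg.matched_filter)
    response = mf_response(enhanced, bank)
    coarse, ga_result = coarse_segment(response, cfg.ga, return_details=True)
    regions = label_regions(coarse, cfg.morph.connectivity)
    if cfg.skip_fine:
        final = coarse
    else:
        final = fine_segment(coarse, cfg.morph)
    return SegmentationResult(
        enhanced=enhanced,
        response=response,
        coarse_mask=coarse,
        fine_mask=final,
        threshold=ga_result.threshold,
        fitness=ga_result.fitness,
        regions=regions,
    )


def run_single(
    image_path,
    config: PipelineConfig | None = None,
    truth_path=None,
    outdir=None,
) -> RunRecord:
    """Segment one file, write outputs, return the run record.

    Writes ``<stem>_mask.png``, ``<stem>_regions.csv`` and
    ``<stem>_record.json`` into ``outdir``; with ``debug`` also the enhanced
    image, response and coarse mask.
    """
    cfg = (config or PipelineConfig()).resolved()
    image_path = Path(image_path)
    t0 = time.perf_counter()
    image = mio.read_image(image_path)
    t_read = time.perf_counter()
    result = run_on_array(image, cfg)
    t_seg = time.perf_counter()

    metrics_dict = None
    if truth_path is not None:
        truth = mio.read_mask(truth_path)
        metrics_dict = evaluate(result.final_mask, truth).as_dict()

    record = RunRecord(
        input_path=str(image_path),
        config=cfg.snapshot(),
        threshold=result.threshold,
        fitness=result.fitness,
        n_regions_coarse=len(result.regions),
        n_regions_final=len(label_regions(result.final_mask, cfg.morph.connectivity)),
        metrics=metrics_dict,
        timings_s={
            "read": round(t_read - t0, 4),
            "segment": round(t_seg - t_read, 4),
        },
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = image_path.stem
        mio.write_mask(outdir / f"{stem}_mask.png", result.final_mask)
        region_table(result.regions, cfg.morph).to_csv(
            outdir / f"{stem}_regions.csv", index=False
        )
        (outdir / f"{stem}_record.json").write_text(record.to_json())
        if cfg.debug:
            mio.write_image_u8(outdir / f"{stem}_enhanced.png", result.enhanced)
            mio.write_image_u8(
                outdir / f"{stem}_response.png", rescale_u8(result.response)
            )
            mio.write_mask(outdir / f"{stem}_coarse.png", result.coarse_mask)
    return record


def run_batch(
    input_dir, config: PipelineConfig | None = None, outdir=None
) -> tuple[list[RunRecord], int]:
    """Segment every PNG/TIFF in a directory.

    Reference masks are looked up in ``input_dir/truth/<same name>``. Writes
    per-image outputs plus ``summary.csv`` (one metrics row per image and
    mean/sd rows). Returns the records and an exit code: 0 on full success,
    2 if some images failed (failures are logged and skipped).
    """
    cfg = (config or PipelineConfig()).resolved()
    input_dir = Path(input_dir)
    paths = sorted(
        p
        for p in input_dir.iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not paths:
        raise ValueError(f"no PNG/TIFF images in {input_dir}")
    truth_dir = input_dir / "truth"
    records: list[RunRecord] = []
    pairs = []
    names = []
    failed = 0
    for p in paths:
        truth_path = truth_dir / p.name if (truth_dir / p.name).exists() else None
        try:
            rec = run_single(p, cfg, truth_path=truth_path, outdir=outdir)
        except Exception as exc:  # noqa: BLE001 — batch must survive bad frames
            warnings.warn(f"{p.name}: {exc}", stacklevel=2)
            failed += 1
            continue
        records.append(rec)
        if truth_path is not None:
            pred = mio.read_mask(Path(outdir) / f"{p.stem}_mask.png") if outdir else None
            if pred is not None:
                pairs.append((pred, mio.read_mask(truth_path)))
                names.append(p.name)
    if outdir is not None and pairs:
        summary = batch_report(pairs)
        summary.to_frame(names).to_csv(Path(outdir) / "summary.csv", index=False)
    return records, (2 if failed else 0)


def config_to_yaml(cfg: PipelineConfig) -> str:
    import yaml

    return yaml.safe_dump(cfg.snapshot(), sort_keys=True)


def config_from_yaml(text: str) -> PipelineConfig:
    import yaml

    data = yaml.safe_load(text) or {}
    cfg = PipelineConfig()
    if "preprocess" in data:
        cfg.preprocess = PreprocessConfig(**data["preprocess"])
    if "matched_filter" in data:
        mf = dict(data["matched_filter"])
        if isinstance(mf.get("scale"), list):
            mf["scale"] = tuple(mf["scale"])
        cfg.matched_filter = MFParams(**mf)
    if "ga" in data:
        cfg.ga = GAConfig(**data["ga"])
    if "morph" in data:
        cfg.morph = FilterParams(**data["morph"])
    for key in ("skip_fine", "debug", "seed"):
        if key in data:
            setattr(cfg, key, data[key])
    return cfg
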