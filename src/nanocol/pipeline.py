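"""Per-synapse orchestration: segmentation -> constrained alignment -> statistics,
plus the colocalization and expansion-factor workflows and their disk outputs
(overlay PNGs, distortion quiver maps, data.txt, summary tables)."""

from __future__ import annotations

import glob as globmod
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .image import Image2D, MultiChannelImage, read_tiff
from .metrics import (compare_groups, coloc_map, macroscopic_expansion_factor,
                      orientation_shift_cosine, pearson_cc, summarize_group)
from .registration import AlignmentResult, estimate_constrained_affine, \
    expansion_factor_structural, apply_transform
from .segmentation import label_and_sort, otsu_threshold, select_synapse

__all__ = [
    "PipelineConfig",
    "SynapseRecord",
    "align_synapse",
    "run_align_pipeline",
    "run_coloc_pipeline",
    "run_exfactor",
]

log = logging.getLogger("nanocol")

DATA_TXT_COLUMNS = [
    "filename", "pcc", "channel_pre", "channel_post", "pcc_before",
    "shift_dx", "shift_dy", "orientation_dot", "accepted", "stage",
]


@dataclass
class PipelineConfig:
    """Configuration of a pipeline run; defaults are the analysis protocol's."""

    inputs: list[str] = field(default_factory=list)   # paths or globs
    channel_map: dict[str, int] = field(
        default_factory=lambda: {"pre": 0, "post": 1, "pan": 2, "trans": 3})
    pixel_size: float | None = None                   # nm, fallback when TIFF lacks it
    min_area_px: int = 300
    min_axis_ratio: float = 2.0
    cosine_threshold: float = 0.3
    require_both_channels: bool = True
    max_shift_frac: float = 0.25
    roi_pad_px: int = 2
    out_dir: str = "nanocol_out"
    write_plots: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        idx = list(self.channel_map.values())
        if len(idx) != len(set(idx)):
            raise ValueError(f"channel indices must be distinct, got {self.channel_map}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def resolve_inputs(self) -> list[str]:
        files: list[str] = []
        for pattern in self.inputs:
            matches = sorted(globmod.glob(str(pattern)))
            files.extend(matches if matches else [str(pattern)])
        return files


@dataclass
class SynapseRecord:
    """One data.txt row: filename, PCC, channels used, and the alignment extras."""

    filename: str
    channel_pre: str = "pre"
    channel_post: str = "post"
    accepted: bool = False
    stage: str = "discarded"
    pcc_before: float = float("nan")
    pcc_after: float = float("nan")
    shift_vector: tuple[float, float] = (float("nan"), float("nan"))
    orientation_dot: float = float("nan")
    notes: str = ""

    def to_row(self) -> list[str]:
        return [
            self.filename,
            f"{self.pcc_after:.6f}",
            self.channel_pre,
            self.channel_post,
            f"{self.pcc_before:.6f}",
            f"{self.shift_vector[0]:.3f}",
            f"{self.shift_vector[1]:.3f}",
            f"{self.orientation_dot:.4f}",
            str(self.accepted),
            self.stage,
        ]


def _load_channels(path: str, config: PipelineConfig) -> MultiChannelImage:
    mc = read_tiff(path, pixel_size=config.pixel_size)
    # map configured channel names onto pages when the TIFF is unnamed
    names = mc.channel_names
    if all(n.startswith("ch") for n in names):
        remap = {}
        for want, idx in config.channel_map.items():
            if idx < len(names):
                remap[want] = mc[names[idx]]
        return MultiChannelImage(remap)
    return mc


def align_synapse(
    mc: MultiChannelImage,
    config: PipelineConfig | None = None,
    qc_dir: str | None = None,
    name: str = "synapse",
) -> tuple[SynapseRecord, AlignmentResult | None]:
    """Run the per-synapse analysis on an in-memory multichannel image.

    Segments the pre and post channels, applies the selection rule, aligns the
    presynaptic (moving) channel onto the postsynaptic (fixed) reference within
    the padded union ROI, and computes the PCCs and the orientation-shift
    cosine. Returns the record plus the full alignment result (``None`` when
    the synapse is discarded).
    """
    config = config or PipelineConfig()
    record = SynapseRecord(filename=name)
    candidates = {}
    for ch in ("pre", "post"):
        if ch not in mc:
            record.notes = f"missing channel '{ch}'"
            return record, None
        img = mc[ch]
        try:
            thr = otsu_threshold(img)
        except ValueError as err:
            record.notes = f"{ch}: {err}"
            return record, None
        regions = label_and_sort(img, thr)
        qc = str(Path(qc_dir) / f"{name}_{ch}_qc.png") if qc_dir else None
        candidates[ch] = select_synapse(
            regions, config.min_area_px, config.min_axis_ratio,
            channel_name=ch, qc_plot_path=qc,
        )

    ok = [candidates[ch].accepted for ch in ("pre", "post")]
    passed = all(ok) if config.require_both_channels else any(ok)
    if not passed:
        fails = [f"{ch}: {candidates[ch].note or candidates[ch].stage}"
                 for ch in ("pre", "post") if not candidates[ch].accepted]
        record.notes = "; ".join(fails)
        record.stage = "discarded"
        return record, None

    ref = candidates["post"] if candidates["post"].accepted else candidates["pre"]
    boxes = [candidates[ch].shape.bounding_box
             for ch in ("pre", "post") if candidates[ch].accepted]
    h, w = mc["post"].shape
    pad = config.roi_pad_px
    roi = (
        max(0, min(b[0] for b in boxes) - pad),
        max(0, min(b[1] for b in boxes) - pad),
        min(h, max(b[2] for b in boxes) + pad),
        min(w, max(b[3] for b in boxes) + pad),
    )
    result = estimate_constrained_affine(
        fixed=mc["post"], moving=mc["pre"], roi=roi,
        max_shift_frac=config.max_shift_frac,
    )
    osc = orientation_shift_cosine(ref.shape.orientation, result.shift_vector,
                                   config.cosine_threshold)
    result.orientation_dot = osc.cosine

    record.accepted = True
    record.stage = ref.stage
    record.pcc_before = result.pcc_before
    record.pcc_after = result.pcc_after
    record.shift_vector = tuple(result.shift_vector)
    record.orientation_dot = osc.cosine
    if osc.note:
        record.notes = osc.note
    return record, result


def _write_data_txt(records: list[SynapseRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(DATA_TXT_COLUMNS) + "\n")
        for rec in records:
            fh.write("\t".join(rec.to_row()) + "\n")


def run_align_pipeline(config: PipelineConfig) -> list[SynapseRecord]:
    """Batch nanocolumn alignment: one record (and one data.txt row) per input
    image, discards included; overlays and distortion maps written per synapse."""
    files = config.resolve_inputs()
    if not files:
        raise ValueError("empty input set")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_used.yaml")

    records = []
    for path in files:
        name = Path(path).stem
        try:
            mc = _load_channels(path, config)
        except Exception as err:  # unreadable file: record and continue
            log.warning("skipping %s: %s", path, err)
            records.append(SynapseRecord(filename=Path(path).name,
                                         notes=f"read error: {err}"))
            continue
        qc_dir = str(out) if config.write_plots else None
        record, result = align_synapse(mc, config, qc_dir=qc_dir, name=name)
        record.filename = Path(path).name
        if result is not None and config.write_plots:
            from . import viz
            aligned = apply_transform(mc["pre"], result.transform)
            viz.save_overlay(mc["post"], mc["pre"], out / f"{name}_before.png")
            viz.save_overlay(mc["post"], aligned, out / f"{name}_overlay.png")
            viz.save_quiver(result.distortion, out / f"{name}_distortion.png")
            with open(out / f"{name}_transform.json", "w") as fh:
                json.dump(_transform_json(result), fh, indent=2)
        records.append(record)

    _write_data_txt(records, out / "data.txt")
    return records


def _transform_json(result: AlignmentResult) -> dict:
    t = result.transform
    return {
        "rotation_rad": t.rotation,
        "shear": t.shear,
        "scale_x": t.scale_x,
        "scale_y": t.scale_y,
        "translation_px": list(t.translation),
        "center_px": list(t.center),
        "convention": "p' = R(theta) Sh(h) S (p - c) + c + t; x=col, y=row",
        "pcc_before": result.pcc_before,
        "pcc_after": result.pcc_after,
        "orientation_dot": result.orientation_dot,
    }


def run_coloc_pipeline(config: PipelineConfig) -> dict:
    """Colocalization of the trans-synaptic channel with the pre and post
    channels (anchored on the trans signal), with group summaries and the
    between-pairing comparison."""
    files = config.resolve_inputs()
    if not files:
        raise ValueError("empty input set")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pcc_post, pcc_pre, rows = [], [], []
    for path in files:
        name = Path(path).stem
        try:
            mc = _load_channels(path, config)
            if "trans" not in mc:
                raise ValueError("no trans channel configured/present")
            overlap_post, p_post = coloc_map(mc["trans"], mc["post"], anchor="a")
            overlap_pre, p_pre = coloc_map(mc["trans"], mc["pre"], anchor="a")
        except Exception as err:
            rows.append({"filename": Path(path).name, "error": str(err)})
            log.warning("coloc failed for %s: %s", path, err)
            continue
        pcc_post.append(p_post)
        pcc_pre.append(p_pre)
        rows.append({"filename": Path(path).name,
                     "pcc_trans_post": p_post, "pcc_trans_pre": p_pre})
        if config.write_plots:
            from . import viz
            viz.save_coloc_map(mc["trans"], mc["post"], overlap_post,
                               out / f"{name}_coloc_post.png")
            viz.save_coloc_map(mc["trans"], mc["pre"], overlap_pre,
                               out / f"{name}_coloc_pre.png")

    if not pcc_post:
        raise ValueError("no usable synapses for colocalization summary")
    report = {"per_synapse": rows, "n_used": len(pcc_post)}
    if len(pcc_post) >= 3:
        report["summary_trans_post"] = asdict(summarize_group(pcc_post))
        report["summary_trans_pre"] = asdict(summarize_group(pcc_pre))
        report["comparison"] = asdict(compare_groups(pcc_post, pcc_pre))
    with open(out / "coloc_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def run_exfactor(
    pre_image: Image2D | None = None,
    post_image: Image2D | None = None,
    pre_diameter: float | None = None,
    post_diameter: float | None = None,
    out_dir: str | None = None,
) -> dict:
    """Expansion-factor report from an image pair (structural), gel diameters
    (macroscopic), or both."""
    report: dict = {}
    if pre_diameter is not None and post_diameter is not None:
        est = macroscopic_expansion_factor(pre_diameter, post_diameter)
        report["macroscopic"] = {"factor": est.factor,
                                 "pre_diameter": pre_diameter,
                                 "post_diameter": post_diameter}
    if pre_image is not None and post_image is not None:
        est = expansion_factor_structural(pre_image, post_image)
        report["structural"] = {
            "factor": est.factor,
            "pcc_similarity": est.pcc_similarity,
            "pcc_affine": est.pcc_affine,
            "distortion_summary": est.distortion_summary,
        }
    if not report:
        raise ValueError("supply an image pair and/or gel diameters")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "exfactor_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
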