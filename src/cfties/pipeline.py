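"""End-to-end orchestration: simulate -> signatures -> score -> evaluate ->
dilute -> monitor.

Stages communicate only through plain-text artifacts in the run directory
(BED, TSV, JSON); each stage reads its inputs back from disk, so any stage
can be rerun in isolation.  A manifest records the effective configuration,
package and library versions, per-stage row counts and output hashes;
reruns with the same configuration and seed reproduce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dilution import DilutionSpec, dilution_experiment
from .errors import ValidationError
from .evaluation import consecutive_deltas, group_compare, loo_cv
from .intervals import read_bed, write_bed
from .quant import FragmentSet, QuantConfig
from .scoring import (
    MARK_K27,
    MARK_K4,
    TiesConfig,
    roc_auc,
    score_sample,
)
from .signatures import (
    CountMatrix,
    SignatureBundle,
    assemble_bundle,
    differential_peaks,
    fusion_occupied_tfbs,
)
from .synthetic import (
    CohortConfig,
    make_decoy_peaks,
    simulate_cell_line_counts,
    simulate_cohort,
    simulate_fusion_peak_sets,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "signatures", "score", "evaluate", "dilute", "monitor")

SHEET_COLUMNS = (
    "sample_id", "patient_id", "label", "mark", "tumor_fraction",
    "draw_date", "status", "fragments",
)


@dataclass
class DifferentialConfig:
    q_max: float = 0.01
    lfc_min_k4: float = 2.0
    lfc_min_k27: float = 1.0
    log2fc_true: float = 4.0
    n_per_group: int = 4
    n_decoy_peaks: int = 360


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    n_trcc: int = 15
    n_ccrcc: int = 15
    n_healthy: int = 9
    longitudinal: Optional[List[List[str]]] = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    ties: TiesConfig = field(default_factory=TiesConfig)
    dilution: DilutionSpec = field(default_factory=DilutionSpec)
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    dilution_tf_min: float = 0.03
    dilution_max_tumors: int = 10

    def __post_init__(self) -> None:
        # the master seed flows into every stage's substreams
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed)
        self.dilution = dataclasses.replace(self.dilution, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Dict) -> "RunConfig":
        raw = dict(raw)
        if "outdir" not in raw:
            raise ValidationError("config must provide 'outdir'")
        kwargs = {}
        for fld, typ in (
            ("cohort", CohortConfig),
            ("quant", QuantConfig),
            ("ties", TiesConfig),
            ("dilution", DilutionSpec),
            ("differential", DifferentialConfig),
        ):
            sub = raw.pop(fld, {})
            if isinstance(sub, dict):
                known = {f.name for f in dataclasses.fields(typ)}
                unknown = set(sub) - known
                if unknown:
                    raise ValidationError(
                        f"unknown keys in '{fld}': {sorted(unknown)}"
                    )
                coerced = {}
                for k, v in sub.items():
                    if isinstance(v, list):
                        v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
                    coerced[k] = v
                kwargs[fld] = typ(**coerced)
            else:
                raise ValidationError(f"'{fld}' must be a mapping")
        known_top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known_top
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_sheet(outdir: Path) -> pd.DataFrame:
    path = outdir / "sample_sheet.tsv"
    if not path.exists():
        raise ValidationError(f"missing artifact {path}; run the simulate stage")
    sheet = pd.read_csv(path, sep="\t", dtype={"status": str}, keep_default_na=False)
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(
            f"sample sheet is missing column(s): {', '.join(missing)}"
        )
    return sheet


def _load_fragments(outdir: Path, sheet: pd.DataFrame) -> Dict[str, Dict[str, FragmentSet]]:
    frags: Dict[str, Dict[str, FragmentSet]] = {}
    for row in sheet.itertuples():
        fs = FragmentSet.from_bed(
            outdir / row.fragments, sample_id=row.sample_id, mark=row.mark
        )
        frags.setdefault(row.sample_id, {})[row.mark] = fs
    return frags


def _load_bundle(outdir: Path) -> SignatureBundle:
    bdir = outdir / "bundle"
    for name in ("k4_up.bed", "k27_up.bed", "tfbs.bed"):
        if not (bdir / name).exists():
            raise ValidationError(
                f"missing artifact {bdir / name}; run the signatures stage"
            )
    return SignatureBundle(
        k4_up=read_bed(bdir / "k4_up.bed", mark=MARK_K4, label="tRCC-up"),
        k27_up=read_bed(bdir / "k27_up.bed", mark=MARK_K27, label="tRCC-up"),
        tfbs=read_bed(bdir / "tfbs.bed", mark="TFBS", label="fusion-occupied"),
    )


# ---------------------------------------------------------------------------
# in-memory building blocks (used by the stages and by scripted analyses)
# ---------------------------------------------------------------------------

def synthetic_cell_line_matrices(
    cohort_cfg: CohortConfig, sites, diff: DifferentialConfig
) -> Dict[str, "CountMatrix"]:
    """Per-mark count matrices over padded consensus sets (true tumor-up
    sites + background decoys, plus rival-subtype "down" sites for the
    enhancer mark)."""
    avoid = [sites.k4_up, sites.k27_up, sites.tfbs_raw, sites.dhs,
             sites.ccrcc_up]
    out: Dict[str, CountMatrix] = {}
    for mark, true_sites, stream in (
        (MARK_K4, sites.k4_up, "k4"),
        (MARK_K27, sites.k27_up, "k27"),
    ):
        decoys = make_decoy_peaks(
            cohort_cfg, avoid, diff.n_decoy_peaks, mark=mark,
            stream=f"decoys-{stream}",
        )
        members = list(true_sites) + list(decoys)
        true_down = sites.ccrcc_up if mark == MARK_K27 else None
        if true_down is not None:
            members += list(true_down)
        consensus = true_sites.replace(members)
        out[mark] = simulate_cell_line_counts(
            cohort_cfg, consensus, true_sites, diff.log2fc_true,
            diff.n_per_group, true_down=true_down, stream=f"counts-{stream}",
        )
    return out


def derive_synthetic_bundle(
    cohort_cfg: CohortConfig,
    sites,
    diff: Optional[DifferentialConfig] = None,
) -> SignatureBundle:
    """Recover the signature bundle from simulated cell-line evidence:
    differential peaks over padded consensus sets for both histone marks,
    plus catalogue-vs-fusion-peak intersection for the TFBS set."""
    diff = diff or DifferentialConfig()
    matrices = synthetic_cell_line_matrices(cohort_cfg, sites, diff)
    ups = {}
    for mark, lfc_min in ((MARK_K4, diff.lfc_min_k4), (MARK_K27, diff.lfc_min_k27)):
        cm = matrices[mark]
        up, _ = differential_peaks(cm, lfc_min=lfc_min, q_max=diff.q_max)
        ups[mark] = cm.peaks.replace([dp.interval for dp in up])
        ups[mark].label = "tRCC-up"
    known, lines = simulate_fusion_peak_sets(cohort_cfg, sites.tfbs_raw)
    tfbs_raw = fusion_occupied_tfbs(known, lines)
    return assemble_bundle(ups[MARK_K4], ups[MARK_K27], tfbs_raw)


def score_cohort(
    samples,
    bundle: SignatureBundle,
    dhs,
    quant_cfg: Optional[QuantConfig] = None,
    ties_cfg: Optional[TiesConfig] = None,
) -> pd.DataFrame:
    """Score a list of :class:`~cfties.synthetic.PlasmaSample` objects."""
    rows = []
    for s in samples:
        res = score_sample(
            s.frags, bundle, dhs, quant_cfg, ties_cfg, sample_id=s.sample_id
        )
        rows.append(
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "label": s.label,
                "tumor_fraction": s.tumor_fraction,
                "draw_date": s.draw_date,
                "status": s.status,
                "s_k4": res.s_k4,
                "s_k27": res.s_k27,
                "s_tfbs": res.s_tfbs,
                "ties": res.ties,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> Dict:
    outdir = Path(cfg.outdir)
    cohort = simulate_cohort(
        cfg.cohort, cfg.n_trcc, cfg.n_ccrcc, cfg.n_healthy,
        longitudinal=cfg.longitudinal,
    )
    cohort.write(outdir)
    sites = cohort.sites

    # cell-line evidence: counts over padded consensus sets + fusion peaks
    matrices = synthetic_cell_line_matrices(cfg.cohort, sites, cfg.differential)
    for mark, cm in matrices.items():
        cm.to_tsv(outdir / f"counts_{mark}.tsv")
        pd.DataFrame({"sample": cm.samples, "group": cm.group}).to_csv(
            outdir / f"cell_line_groups_{mark}.tsv", sep="\t", index=False
        )

    known, lines = simulate_fusion_peak_sets(cfg.cohort, sites.tfbs_raw)
    write_bed(known, outdir / "known_tfbs.bed")
    for i, line in enumerate(lines, start=1):
        write_bed(line, outdir / f"fusion_peaks_line{i}.bed")
    return {
        "n_samples": len(cohort.samples),
        "n_fragment_files": int(2 * len(cohort.samples)),
    }


def stage_signatures(cfg: RunConfig) -> Dict:
    outdir = Path(cfg.outdir)
    diff = cfg.differential
    ups = {}
    for mark, lfc_min in ((MARK_K4, diff.lfc_min_k4), (MARK_K27, diff.lfc_min_k27)):
        groups = pd.read_csv(
            outdir / f"cell_line_groups_{mark}.tsv", sep="\t"
        )["group"].tolist()
        cm = CountMatrix.from_tsv(
            outdir / f"counts_{mark}.tsv", group=groups, mark=mark
        )
        up, _down = differential_peaks(cm, lfc_min=lfc_min, q_max=diff.q_max)
        ups[mark] = cm.peaks.replace([dp.interval for dp in up])
        ups[mark].label = "tRCC-up"

    known = read_bed(outdir / "known_tfbs.bed", mark="TFBS", label="known")
    lines = []
    i = 1
    while (outdir / f"fusion_peaks_line{i}.bed").exists():
        lines.append(read_bed(outdir / f"fusion_peaks_line{i}.bed", mark="TFE3"))
        i += 1
    tfbs_raw = fusion_occupied_tfbs(known, lines)
    bundle = assemble_bundle(ups[MARK_K4], ups[MARK_K27], tfbs_raw)

    bdir = outdir / "bundle"
    bdir.mkdir(parents=True, exist_ok=True)
    write_bed(bundle.k4_up, bdir / "k4_up.bed")
    write_bed(bundle.k27_up, bdir / "k27_up.bed")
    write_bed(bundle.tfbs, bdir / "tfbs.bed")
    summary = {
        "n_k4_up": len(bundle.k4_up),
        "n_k27_up": len(bundle.k27_up),
        "n_tfbs_raw": len(tfbs_raw),
        "n_tfbs_after_dedup": len(bundle.tfbs),
        "n_tfbs_discarded": len(tfbs_raw) - len(bundle.tfbs),
    }
    with open(outdir / "signatures.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def stage_score(cfg: RunConfig) -> Dict:
    outdir = Path(cfg.outdir)
    sheet = _read_sheet(outdir)
    bundle = _load_bundle(outdir)
    dhs = read_bed(outdir / "sites" / "dhs.bed", mark="DHS")
    frags = _load_fragments(outdir, sheet)

    meta = sheet.drop_duplicates("sample_id").set_index("sample_id")
    rows = []
    for sample_id, by_mark in frags.items():
        res = score_sample(
            by_mark, bundle, dhs, cfg.quant, cfg.ties, sample_id=sample_id
        )
        m = meta.loc[sample_id]
        rows.append(
            {
                "sample_id": sample_id,
                "patient_id": m["patient_id"],
                "label": m["label"],
                "tumor_fraction": m["tumor_fraction"],
                "draw_date": m["draw_date"],
                "status": m["status"],
                "s_k4": res.s_k4,
                "s_k27": res.s_k27,
                "s_tfbs": res.s_tfbs,
                "ties": res.ties,
            }
        )
    ties = pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)
    ties.to_csv(outdir / "ties.tsv", sep="\t", index=False)
    return {"n_scored": len(ties)}


def _cross_sectional(ties: pd.DataFrame) -> pd.DataFrame:
    return ties[ties["status"] == ""]


def stage_evaluate(cfg: RunConfig) -> Dict:
    outdir = Path(cfg.outdir)
    ties = pd.read_csv(outdir / "ties.tsv", sep="\t", keep_default_na=False)
    cs = _cross_sectional(ties)
    out: Dict = {}
    for contrast, neg in (("trcc_vs_healthy", "healthy"), ("trcc_vs_ccrcc", "ccRCC")):
        sub = cs[cs["label"].isin(["tRCC", neg])]
        if sub["label"].nunique() < 2:
            continue
        roc = roc_auc(sub["ties"].tolist(), sub["label"].tolist(), positive="tRCC")
        out[f"auc_{contrast}"] = roc.auc
        pd.DataFrame(roc.points, columns=["fpr", "tpr"]).to_csv(
            outdir / f"roc_{contrast}.tsv", sep="\t", index=False
        )
    sub = cs[cs["label"].isin(["tRCC", "healthy"])]
    if sub["label"].nunique() == 2 and len(sub) >= 3:
        cv = loo_cv(sub["ties"].tolist(), sub["label"].tolist(), positive="tRCC")
        out["loocv"] = {
            "precision": cv.precision,
            "recall": cv.recall,
            "specificity": cv.specificity,
            "mean_threshold": cv.mean_threshold,
        }
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return out


def stage_dilute(cfg: RunConfig) -> Dict:
    outdir = Path(cfg.outdir)
    sheet = _read_sheet(outdir)
    ties = pd.read_csv(outdir / "ties.tsv", sep="\t", keep_default_na=False)
    cs = _cross_sectional(ties)
    bundle = _load_bundle(outdir)
    dhs = read_bed(outdir / "sites" / "dhs.bed", mark="DHS")
    frags = _load_fragments(outdir, sheet)

    tum = cs[(cs["label"] == "tRCC") & (cs["tumor_fraction"] > cfg.dilution_tf_min)]
    tum = tum.sort_values("sample_id").head(cfg.dilution_max_tumors)
    heal = cs[cs["label"] == "healthy"].sort_values("sample_id")
    if tum.empty or heal.empty:
        raise ValidationError(
            "dilution needs tumor samples above the tumor-fraction floor and "
            "healthy samples"
        )
    tumors = [
        (r.sample_id, float(r.tumor_fraction), frags[r.sample_id])
        for r in tum.itertuples()
    ]
    healthies = [(r.sample_id, frags[r.sample_id]) for r in heal.itertuples()]
    healthy_ties = heal.set_index("sample_id").loc[
        [h[0] for h in healthies], "ties"
    ].tolist()

    lod = dilution_experiment(
        tumors, healthies, cfg.dilution, bundle, dhs,
        quant_cfg=cfg.quant, ties_cfg=cfg.ties, healthy_ties=healthy_ties,
    )
    pd.DataFrame(
        [
            {
                "tumor_id": m.tumor_id,
                "healthy_id": m.healthy_id,
                "dl": m.dl,
                "n_reads": m.n_reads,
                "expected_tf": m.expected_tf,
                "ties": m.ties,
            }
            for m in lod.mixtures
        ]
    ).to_csv(outdir / "dilution_mixtures.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "bin": b.label(),
                "n": b.n,
                "median_ties": float(np.median(b.ties_values)) if b.n else np.nan,
                "p_value": b.p_value,
            }
            for b in lod.bins
        ]
    ).to_csv(outdir / "dilution_bins.tsv", sep="\t", index=False)
    summary = {
        "n_tumors": len(tumors),
        "n_healthies": len(healthies),
        "n_dilution_levels": len(cfg.dilution.dilution_levels),
        "n_mixtures": len(lod.mixtures),
        "lod_bin": lod.lod_bin.label() if lod.lod_bin else None,
    }
    with open(outdir / "dilution.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def stage_monitor(cfg: RunConfig) -> Dict:
    outdir = Path(cfg.outdir)
    ties = pd.read_csv(outdir / "ties.tsv", sep="\t", keep_default_na=False)
    counts = ties.groupby("patient_id")["sample_id"].count()
    multi = counts[counts >= 2].index
    rows = ties[ties["patient_id"].isin(multi)]
    records = rows.rename(columns={"draw_date": "draw_date"}).to_dict("records")
    pairs = consecutive_deltas(records)
    df = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "t0": p.t0,
                "t1": p.t1,
                "delta_ties_pct": p.delta_ties,
                "delta_tf": p.delta_tf,
                "status": p.status,
            }
            for p in pairs
        ]
    )
    df.to_csv(outdir / "monitoring_pairs.tsv", sep="\t", index=False)
    out: Dict = {"n_pairs": len(pairs)}
    prog = [p.delta_ties for p in pairs if p.status == "progression"]
    other = [p.delta_ties for p in pairs if p.status in ("stable", "response")]
    if prog and other:
        stat, pval = group_compare(prog, other)
        out.update(
            {
                "n_progression_pairs": len(prog),
                "n_other_pairs": len(other),
                "delta_ties_p_value": pval,
            }
        )
    with open(outdir / "monitoring.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "signatures": stage_signatures,
    "score": stage_score,
    "evaluate": stage_evaluate,
    "dilute": stage_dilute,
    "monitor": stage_monitor,
}

_HASH_ARTIFACTS = (
    "ties.tsv",
    "sample_sheet.tsv",
    "dilution_mixtures.tsv",
    "monitoring_pairs.tsv",
)


def run(cfg: RunConfig, stages: Optional[Sequence[str]] = None) -> Dict:
    """Execute the requested stages in dependency order and write the run
    manifest.  Stages not requested must already have produced their
    artifacts in ``cfg.outdir``."""
    stages = list(stages or ALL_STAGES)
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ValidationError(f"unknown stage(s): {', '.join(unknown)}")
    ordered = [s for s in ALL_STAGES if s in stages]
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: Dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": cfg.to_dict(),
        "stages": {},
    }
    for stage in ordered:
        logger.info("running stage %s", stage)
        manifest["stages"][stage] = _STAGE_FUNCS[stage](cfg)
    manifest["artifact_sha256"] = {
        name: _sha256(outdir / name)
        for name in _HASH_ARTIFACTS
        if (outdir / name).exists()
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
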