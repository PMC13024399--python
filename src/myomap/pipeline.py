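"""End-to-end synthetic study: phantom cohort -> colormaps -> reader panel
-> MRMC report.

A run is fully reproducible from its config and seed alone: the global
seed fans out to per-stage seeds (cohort synthesis, design allocation,
reader simulation) through ``numpy.random.SeedSequence.spawn``, so each
stage can also be re-run independently with its derived seed.  The config
hash (SHA-256 of the canonical YAML serialization) is recorded in the run
manifest for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .colormap import ColormapParams, compute_deviation_map
from .datasets import STUDY_COHORT_MIX, default_reader_panel
from .mrmc import (
    aggregate,
    allocate_design,
    confusion,
    discordant_counts,
    format_reclass_table,
    kappa_matrix,
    mcnemar,
    metrics,
    nri,
    reclass_from_records,
    subgroup_metrics,
    territory_metrics,
    time_compare,
)
from .phantom import PhantomSpec, ReaderOperatingPoint, generate_cohort, simulate_readers

logger = logging.getLogger("myomap")

__all__ = ["RunConfig", "ReportBundle", "analyze_records", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one synthetic study run."""

    n_stemi: int = STUDY_COHORT_MIX[0]
    n_nstemi: int = STUDY_COHORT_MIX[1]
    n_none: int = STUDY_COHORT_MIX[2]
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    colormap: ColormapParams = field(default_factory=ColormapParams)
    readers: list[ReaderOperatingPoint] = field(default_factory=default_reader_panel)
    seed: int = 0
    write_volumes: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"] = dataclasses.asdict(self.phantom)
        d["colormap"] = dataclasses.asdict(self.colormap)
        d["readers"] = [dataclasses.asdict(p) for p in self.readers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d:
            p = dict(d["phantom"])
            for k in ("grid_shape", "voxel_size"):
                if k in p and p[k] is not None:
                    p[k] = tuple(p[k])
            if p.get("inner_axes_mm") is not None:
                p["inner_axes_mm"] = tuple(p["inner_axes_mm"])
            d["phantom"] = PhantomSpec(**p)
        if "colormap" in d:
            d["colormap"] = ColormapParams(**d["colormap"])
        if "readers" in d:
            d["readers"] = [ReaderOperatingPoint(**r) for r in d["readers"]]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def sha256(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class ReportBundle:
    """In-memory MRMC report: tables mirrored to disk by run_pipeline."""

    reader_table: pd.DataFrame
    averages: pd.DataFrame
    kappa: dict[str, pd.DataFrame]
    territory: dict[str, pd.DataFrame]
    subgroup: pd.DataFrame
    reclass_text: dict[str, str]
    times: pd.DataFrame


def _safe_nri(with_rec, without_rec, truth) -> float:
    try:
        return nri(reclass_from_records(with_rec, without_rec, truth))
    except ValueError:
        return float("nan")


def analyze_records(records: pd.DataFrame, truth: pd.DataFrame) -> ReportBundle:
    """Compute the full MRMC report from reading records and adjudications.

    Per reader and condition: the 2x2 confusion, the five diagnostic
    proportions, McNemar p-values for the paired with/without sensitivity
    and specificity comparisons, and the binary NRI (cell-sum
    denominators).  Pooled: pairwise kappa matrices, per-territory metrics
    and reading-time comparisons per condition.  Metrics with empty
    denominators come back NaN rather than failing the run.
    """
    readers = sorted(records.reader_id.unique())
    rows = []
    avg_acc: dict[str, dict[str, list[float]]] = {}
    reclass_text = {}
    for reader in readers:
        per_cond = {}
        for cond in ("with_colormap", "without_colormap"):
            sub = records[(records.reader_id == reader) & (records.condition == cond)]
            per_cond[cond] = sub
        m = {}
        for cond, sub in per_cond.items():
            m[cond] = metrics(confusion(sub, truth))
        b_s, c_s = discordant_counts(
            per_cond["with_colormap"], per_cond["without_colormap"], truth, "cases"
        )
        b_sp, c_sp = discordant_counts(
            per_cond["with_colormap"], per_cond["without_colormap"], truth, "noncases"
        )
        p_sens = mcnemar(b_s, c_s).p_value
        p_spec = mcnemar(b_sp, c_sp).p_value
        reader_nri = _safe_nri(
            per_cond["with_colormap"], per_cond["without_colormap"], truth
        )
        reclass_text[reader] = format_reclass_table(
            reclass_from_records(
                per_cond["with_colormap"], per_cond["without_colormap"], truth
            )
        )
        for cond in ("without_colormap", "with_colormap"):
            rows.append(
                {
                    "reader_id": reader,
                    "condition": cond,
                    **m[cond]._asdict(),
                    "mcnemar_p_sensitivity": p_sens,
                    "mcnemar_p_specificity": p_spec,
                    "nri": reader_nri,
                }
            )
    reader_table = pd.DataFrame(rows)

    averages = (
        reader_table.groupby("condition", sort=True)[
            ["sensitivity", "specificity", "accuracy", "ppv", "npv", "nri"]
        ]
        .mean()
        .reset_index()
    )

    kappa = {
        cond: kappa_matrix(records, cond)
        for cond in ("with_colormap", "without_colormap")
    }
    territory = {
        cond: territory_metrics(records[records.condition == cond], truth)
        for cond in ("with_colormap", "without_colormap")
    }

    sub_rows = []
    for subgroup in ("STEMI", "NSTEMI"):
        if not truth.adjudication.eq(subgroup).any():
            continue
        for reader in readers:
            for cond in ("with_colormap", "without_colormap"):
                sub = records[
                    (records.reader_id == reader) & (records.condition == cond)
                ]
                sm = subgroup_metrics(sub, truth, subgroup)
                sub_rows.append(
                    {
                        "subgroup": subgroup,
                        "reader_id": reader,
                        "condition": cond,
                        "sensitivity": sm.sensitivity,
                        "ppv": sm.ppv,
                    }
                )
    subgroup = pd.DataFrame(
        sub_rows, columns=["subgroup", "reader_id", "condition", "sensitivity", "ppv"]
    )

    time_rows = []
    paired_all = records.pivot_table(
        index=["reader_id", "case_id"], columns="condition", values="time_s"
    ).dropna()
    tc = time_compare(paired_all["with_colormap"], paired_all["without_colormap"])
    time_rows.append({"reader_id": "all", **tc._asdict()})
    for reader in readers:
        sub = paired_all.loc[reader]
        tc = time_compare(sub["with_colormap"], sub["without_colormap"])
        time_rows.append({"reader_id": reader, **tc._asdict()})
    times = pd.DataFrame(time_rows)

    return ReportBundle(
        reader_table=reader_table,
        averages=averages,
        kappa=kappa,
        territory=territory,
        subgroup=subgroup,
        reclass_text=reclass_text,
        times=times,
    )


def _write_report(bundle: ReportBundle, out: Path, config_hash: str) -> None:
    report = out / "report"
    report.mkdir(parents=True, exist_ok=True)
    bundle.reader_table.to_csv(report / "reader_metrics.csv", index=False, lineterminator="\n")
    bundle.averages.to_csv(report / "averages.csv", index=False, lineterminator="\n")
    for cond, km in bundle.kappa.items():
        km.to_json(report / f"kappa_{cond}.json", orient="split", indent=2)
    for cond, tm in bundle.territory.items():
        tm.to_csv(report / f"territory_{cond}.csv", lineterminator="\n")
    bundle.subgroup.to_csv(report / "subgroup_metrics.csv", index=False, lineterminator="\n")
    bundle.times.to_csv(report / "times.csv", index=False, lineterminator="\n")
    for reader, text in bundle.reclass_text.items():
        (report / f"reclassification_{reader}.txt").write_text(text + "\n")
    (report / "provenance.json").write_text(
        json.dumps({"config_sha256": config_hash}, indent=2) + "\n"
    )


def run_pipeline(config: RunConfig, out: str | Path) -> ReportBundle:
    """Run the full synthetic study and write its artifacts under ``out``.

    Stages: phantom cohort synthesis (with truth and perturbed automatic
    masks), deviation-map computation per case, crossed design allocation,
    reader-panel simulation, and the MRMC report.  Identical config + seed
    reproduce byte-identical CSV outputs.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    config_hash = config.sha256()
    stage_seeds = [
        int(s % 2**31)
        for s in np.random.SeedSequence(int(config.seed)).generate_state(4)[1:]
    ]
    cohort_seed, design_seed, reader_seed = stage_seeds
    logger.info("stage: cohort synthesis (seed %d)", cohort_seed)
    cohort = generate_cohort(
        config.n_stemi, config.n_nstemi, config.n_none, config.phantom, seed=cohort_seed
    )

    from .phantom import cohort_truth

    truth = cohort_truth(cohort)
    mio.write_truth(truth, out / "truth.csv")

    if config.write_volumes:
        logger.info("stage: volumes, masks and deviation maps")
        vol_dir = out / "cases"
        vol_dir.mkdir(exist_ok=True)
        for case in cohort:
            stem = vol_dir / case.case_id
            mio.write_volume(case.volume, f"{stem}_ct.nii.gz")
            mio.write_mask(case.myo_mask_truth, f"{stem}_myo.nii.gz", case.volume.spacing)
            mio.write_mask(case.myo_mask_auto, f"{stem}_myo_auto.nii.gz", case.volume.spacing)
            if case.lesion_mask.any():
                mio.write_mask(case.lesion_mask, f"{stem}_lesion.nii.gz", case.volume.spacing)
            dmap = compute_deviation_map(case.volume, case.myo_mask_truth, config.colormap)
            mio.write_map(dmap, f"{stem}_map.nii.gz")

    logger.info("stage: design allocation (seed %d)", design_seed)
    reader_ids = sorted({p.reader_id for p in config.readers})
    design = allocate_design(reader_ids, list(truth.case_id), seed=design_seed)

    logger.info("stage: reader simulation (seed %d)", reader_seed)
    records = simulate_readers(truth, config.readers, design, seed=reader_seed)
    mio.write_records(records, out / "records.csv")

    logger.info("stage: MRMC report")
    bundle = analyze_records(records, truth)
    _write_report(bundle, out, config_hash)
    config.to_yaml(out / "config.yaml")
    return bundle
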