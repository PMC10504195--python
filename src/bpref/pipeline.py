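"""End-to-end pipeline: simulate/load → select → Z-score → filter → fit →
reference tables → diagnostics, with provenance.

Every run writes a manifest (``manifest.json``) listing the config, the
seed, package versions and a SHA-256 hash of every output file, so a run
can be reproduced and verified hash-for-hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import apply_exclusions, cohort_summary
from .diagnostics import fitcurve_data, qq_coordinates, residual_density
from .growth import GrowthStandard, synthetic_growth_standard
from .lms import LMSModel, default_edf_grid
from .polynomial import QuarticBPModel
from .simulate import (
    BP_PERCENTILES,
    DEFAULT_SEED,
    HEIGHT_PERCENTILES,
    SimulationConfig,
    generate_cohort,
    read_cohort_csv,
    write_cohort_csv,
)
from .tables import build_reference_table, compare_tables

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Settings for one pipeline run.

    Either ``cohort_csv`` (with optional ``growth_standard_csv``) or
    ``simulate`` must be provided, not neither.
    """

    out_dir: str = "bpref_run"
    cohort_csv: str | None = None
    growth_standard_csv: str | None = None
    simulate: SimulationConfig | None = None
    model_kinds: tuple = ("lms", "polynomial")
    edf_grid: list | None = None
    height_percentiles: tuple = HEIGHT_PERCENTILES
    bp_percentiles: tuple = BP_PERCENTILES
    seed: int = DEFAULT_SEED
    log_level: str = "INFO"

    def __post_init__(self):
        if self.cohort_csv is None and self.simulate is None:
            raise ValueError("provide a cohort CSV or a simulation config")
        if self.edf_grid is not None and len(self.edf_grid) == 0:
            raise ValueError("edf grid must be non-empty")
        bad = set(self.model_kinds) - {"lms", "polynomial"}
        if bad:
            raise ValueError(f"unknown model kinds: {bad}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        d["model_kinds"] = list(self.model_kinds)
        d["height_percentiles"] = list(self.height_percentiles)
        d["bp_percentiles"] = list(self.bp_percentiles)
        if self.edf_grid is not None:
            d["edf_grid"] = [list(t) for t in self.edf_grid]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = SimulationConfig.from_dict(d["simulate"])
        for k in ("model_kinds", "height_percentiles", "bp_percentiles"):
            if k in d:
                d[k] = tuple(d[k])
        if d.get("edf_grid") is not None:
            d["edf_grid"] = [tuple(t) for t in d["edf_grid"]]
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a bundle of in-memory results.

    Writes to ``config.out_dir``: the (simulated) cohort, flow report,
    cohort summary, model exports, reference tables (wide + long),
    diagnostics CSVs and a provenance manifest.  Identical config+seed
    reproduce identical files.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    bundle: dict = {}
    stage = "init"
    try:
        stage = "load"
        if config.cohort_csv is not None:
            cohort = read_cohort_csv(config.cohort_csv)
            standard = (
                GrowthStandard.from_csv(config.growth_standard_csv)
                if config.growth_standard_csv
                else synthetic_growth_standard()
            )
        else:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            standard = synthetic_growth_standard()
            cohort = generate_cohort(sim, standard)
            write_cohort_csv(cohort, out / "cohort.csv")
            written.append(out / "cohort.csv")
        log.info("cohort: %d records", len(cohort))

        stage = "filter"
        sbp_set, dbp_set, flow = apply_exclusions(cohort, standard)
        (out / "flow.json").write_text(json.dumps(flow.to_dict(), indent=1))
        (out / "flow.txt").write_text(flow.to_text())
        written += [out / "flow.json", out / "flow.txt"]
        summary = cohort_summary(sbp_set, dbp_set)
        summary.to_csv(out / "cohort_summary.csv", index=False)
        written.append(out / "cohort_summary.csv")
        bundle.update(flow=flow, summary=summary, sbp_set=sbp_set, dbp_set=dbp_set)
        for name, s in (("sbp", sbp_set), ("dbp", dbp_set)):
            s.to_csv(out / f"analyzed_{name}.csv", index=False)
            written.append(out / f"analyzed_{name}.csv")

        stage = "fit"
        grid = config.edf_grid if config.edf_grid is not None else default_edf_grid()
        fits: dict = {}
        tables: dict = {}
        for outcome, data in (("sbp", sbp_set), ("dbp", dbp_set)):
            for sex in sorted(data["sex"].unique()):
                sub = data[data["sex"] == sex]
                key = (sex, outcome)
                fits[key] = {}
                if "lms" in config.model_kinds:
                    res = LMSModel(
                        sub["zht"].to_numpy(), sub["bp"].to_numpy(), sex=sex, outcome=outcome
                    ).fit(edf_grid=grid)
                    fits[key]["lms"] = res
                    res.export(
                        out / f"lms_coefs_{sex}_{outcome}.csv",
                        out / f"lms_model_{sex}_{outcome}.json",
                    )
                    written += [
                        out / f"lms_coefs_{sex}_{outcome}.csv",
                        out / f"lms_model_{sex}_{outcome}.json",
                    ]
                if "polynomial" in config.model_kinds:
                    pres = QuarticBPModel(
                        sub["zht"].to_numpy(), sub["bp"].to_numpy(), sex=sex, outcome=outcome
                    ).fit()
                    fits[key]["polynomial"] = pres
                    pres.export(out / f"poly_coefs_{sex}_{outcome}.csv")
                    written.append(out / f"poly_coefs_{sex}_{outcome}.csv")

                stage = "tables"
                for kind, res in fits[key].items():
                    tab = build_reference_table(
                        res,
                        config.height_percentiles,
                        config.bp_percentiles,
                        sex=sex,
                        outcome=outcome,
                    )
                    tables[(sex, outcome, kind)] = tab
                    path = out / f"reference_{kind}_{sex}_{outcome}.csv"
                    tab.to_wide_csv(path)
                    written.append(path)

                stage = "diagnostics"
                zht_v = sub["zht"].to_numpy()
                bp_v = sub["bp"].to_numpy()
                for kind, res in fits[key].items():
                    if kind == "lms":
                        z, _ = res.z_residuals()
                    else:
                        z = (bp_v - res.predict_mean(zht_v)) / res.resid_sd
                    qq = qq_coordinates(z)
                    fc = fitcurve_data(res, zht_v, bp_v)
                    dens = residual_density(z)
                    for suffix, frame in (("qq", qq), ("fitcurve", fc), ("density", dens)):
                        p = out / f"diag_{kind}_{suffix}_{sex}_{outcome}.csv"
                        frame.to_csv(p, index=False)
                        written.append(p)
                stage = "fit"

        # long-format tidy table across all strata/models
        if tables:
            long = pd.concat([t.to_long() for t in tables.values()], ignore_index=True)
            long.to_csv(out / "reference_long.csv", index=False)
            written.append(out / "reference_long.csv")
        # model agreement report
        comparisons = {}
        for (sex, outcome, kind) in list(tables):
            if kind == "lms" and (sex, outcome, "polynomial") in tables:
                comparisons[f"{sex}_{outcome}"] = {
                    k: v
                    for k, v in compare_tables(
                        tables[(sex, outcome, "lms")], tables[(sex, outcome, "polynomial")]
                    ).items()
                    if k != "diff"
                }
        if comparisons:
            (out / "model_agreement.json").write_text(json.dumps(comparisons, indent=1))
            written.append(out / "model_agreement.json")

        bundle.update(fits=fits, tables=tables, comparisons=comparisons)

        stage = "provenance"
        manifest = {
            "bpref_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "files": {p.name: _sha256(p) for p in sorted(set(written))},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        bundle["manifest"] = manifest
        return bundle
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
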