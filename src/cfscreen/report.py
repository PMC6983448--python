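"""Baseline cohort tables and end-to-end pipeline orchestration.

``run_all`` wires the stages together — simulate, match both arms, screen
both arms, compare effect profiles, burden analysis, sensitivity suite and
familial validation — writing every output as delimited text plus a JSON run
manifest with file digests and per-stage seeds (master seed + stage index).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import burden_ors, compare_log_ors
from .config import AGE_BAND_LABELS, GeneratorConfig, MatchPolicy
from .errors import ConfigurationError, DataError
from .io import write_table
from .matching import build_matched_sets
from .screen import count_significant, run_screen, run_validation_screen
from .sens import FdrConfig, MisclassConfig, ascertainment_filter, empirical_fdr, \
    misclassification_sweep
from .synth import generate_catalog, generate_families, generate_population


def baseline_table(population: pd.DataFrame, cohort_labels=("carrier", "cf")) -> pd.DataFrame:
    """Cohort characteristics: n, female n (%), age-band n (%), enrollment months.

    Percentages are reported to 1 decimal place; months summarized by min,
    max, mean (1 dp) and median.
    """
    known = set(population["group"])
    rows = []
    for label in cohort_labels:
        if label not in known:
            raise ConfigurationError(f"unknown cohort label {label!r}")
        sub = population[population["group"] == label]
        n = len(sub)
        rec = {"cohort": label, "n": n}
        nf = int((sub["sex"] == "F").sum())
        rec["female_n"] = nf
        rec["female_pct"] = round(100.0 * nf / n, 1)
        for band in AGE_BAND_LABELS:
            nb = int((sub["age_band"] == band).sum())
            rec[f"age_{band}_n"] = nb
            rec[f"age_{band}_pct"] = round(100.0 * nb / n, 1)
        months = sub["enroll_months"]
        rec["months_min"] = int(months.min())
        rec["months_max"] = int(months.max())
        rec["months_mean"] = round(float(months.mean()), 1)
        rec["months_median"] = float(months.median())
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class RunManifest:
    seed: int
    version: str = __version__
    timestamp: float = 0.0
    stages: dict = field(default_factory=dict)  # stage -> {seed, outputs: {file: digest}, notes}

    def record(self, stage: str, seed: int, outputs: dict, note: str = "") -> None:
        self.stages[stage] = {"seed": seed, "outputs": outputs, "note": note}

    def core(self) -> dict:
        """Manifest content excluding the wall-clock timestamp (for rerun audits)."""
        return {"seed": self.seed, "version": self.version, "stages": self.stages}

    def to_json(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump({**self.core(), "timestamp": self.timestamp}, fh, indent=2)
        return path


def _file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _screen_outputs(screen) -> pd.DataFrame:
    return screen.table


def run_all(
    config: GeneratorConfig,
    out_dir,
    seed: int | None = None,
    *,
    M: int = 5,
    alpha: float = 0.05,
    fdr_reps: int = 100,
    misclass_reps: int = 5,
    misclass_grid=None,
    n_family_pairs: int | None = None,
    policy: MatchPolicy = MatchPolicy(),
) -> RunManifest:
    """Run the full pipeline, writing all outputs under ``out_dir``.

    Per-stage seeds are derived as ``master_seed + stage_index`` so streams
    are independent and every stage is individually reproducible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(config.seed if seed is None else seed) % (2**31 - 100)
    config = GeneratorConfig.from_dict({**config.to_dict(), "seed": master})
    manifest = RunManifest(seed=master, timestamp=time.time())

    def emit(stage, seed_used, note="", **tables):
        outputs = {}
        for name, df in tables.items():
            p = write_table(df, out / f"{name}.csv")
            outputs[f"{name}.csv"] = _file_digest(p)
        manifest.record(stage, seed_used, outputs, note)

    def stage_fail(stage, exc):
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    # simulate
    try:
        catalog = generate_catalog(config)
        population = generate_population(catalog, config)
    except Exception as e:  # noqa: BLE001 - stage context requested by contract
        stage_fail("simulate", e)
    emit("simulate", master, catalog=catalog, population=population)

    # match both arms
    sets = {}
    for i, arm in enumerate(("carrier", "cf")):
        try:
            sets[arm] = build_matched_sets(population, index_group=arm, M=M,
                                           seed=master + 1 + i, policy=policy)
        except Exception as e:
            stage_fail(f"match_{arm}", e)
        emit(f"match_{arm}", master + 1 + i, **{f"sets_{arm}": sets[arm]})

    # screen both arms
    screens = {}
    for arm in ("carrier", "cf"):
        try:
            screens[arm] = run_screen(population, sets[arm], catalog, arm)
        except Exception as e:
            stage_fail(f"screen_{arm}", e)
        emit(f"screen_{arm}", master,
             note=f"n_significant={count_significant(screens[arm], alpha)}",
             **{f"screen_{arm}": screens[arm].table})

    # compare effect profiles
    try:
        comp = compare_log_ors(screens["carrier"], screens["cf"])
        comp_df = pd.DataFrame([{
            "pearson_r": comp.pearson_r, "slope": comp.slope,
            "intercept": comp.intercept, "slope_p": comp.slope_p,
            "n_conditions_used": comp.n_conditions_used,
            "n_excluded": len(comp.excluded_conditions),
        }])
        emit("compare", master, compare=comp_df)
    except DataError as e:
        manifest.record("compare", master, {}, note=f"skipped: {e}")

    # burden, both axes, carrier arm
    for axis in ("conditions", "systems"):
        try:
            b = burden_ors(population, sets["carrier"], catalog, axis)
        except Exception as e:
            stage_fail(f"burden_{axis}", e)
        emit(f"burden_{axis}", master, **{f"burden_{axis}": b.table})

    # sensitivity: empirical FDR on the carrier sets
    try:
        fdr_mean, fdr_counts = empirical_fdr(
            population, sets["carrier"], catalog,
            FdrConfig(alpha=alpha, n_reps=fdr_reps, seed=master + 10))
        emit("sens_fdr", master + 10,
             note=f"mean_significant={fdr_mean:.3f}",
             sens_fdr=pd.DataFrame({"rep": np.arange(len(fdr_counts)),
                                    "n_significant": fdr_counts}))
    except Exception as e:
        stage_fail("sens_fdr", e)

    # sensitivity: misclassification sweep (desk scale)
    try:
        n_cf_pool = int((population["true_status"] == "cf").sum())
        grid = misclass_grid
        if grid is None:
            top = min(n_cf_pool, max(50, config.n_carriers // 4))
            grid = sorted({0, top // 2, top})
        sweep = misclassification_sweep(
            population, catalog,
            MisclassConfig(m_grid=list(grid), n_reps=misclass_reps, seed=master + 11),
            targets=screens["carrier"],
            cohort_size=min(config.n_carriers, 2000), M=M, policy=policy)
        emit("sens_misclass", master + 11, sens_misclass=sweep)
    except Exception as e:
        stage_fail("sens_misclass", e)

    # sensitivity: ascertainment exclusion re-screen
    try:
        filtered = ascertainment_filter(population)
        sets_f = build_matched_sets(filtered, index_group="carrier", M=M,
                                    seed=master + 12, policy=policy)
        scr_f = run_screen(filtered, sets_f, catalog, "carrier")
        emit("sens_ascertain", master + 12,
             note=f"n_carriers_kept={int((filtered['group'] == 'carrier').sum())}",
             screen_carrier_unascertained=scr_f.table)
    except Exception as e:
        stage_fail("sens_ascertain", e)

    # familial validation cohort
    try:
        fam_cfg = GeneratorConfig.from_dict(
            {**config.to_dict(), "seed": master + 13})
        n_pairs = n_family_pairs if n_family_pairs is not None else config.n_family_pairs
        fam = generate_families(catalog, fam_cfg, n_pairs)
        pool = population[population["group"] == "control_pool"]
        for c in fam.columns:
            if c not in pool.columns:
                pool = pool.assign(**{c: pd.NA})
        vpop = pd.concat([fam, pool[fam.columns]], ignore_index=True)
        scr_v = run_validation_screen(vpop, catalog, M=M, seed=master + 14,
                                      policy=policy)
        emit("validate_cohort", master + 13,
             note=f"n_significant={count_significant(scr_v, alpha)}",
             screen_validation=scr_v.table)
    except Exception as e:
        stage_fail("validate_cohort", e)

    # report bundle
    try:
        base = baseline_table(population, ("carrier", "cf"))
        emit("report", master, baseline=base)
    except Exception as e:
        stage_fail("report", e)

    manifest.to_json(out / "manifest.json")
    return manifest
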