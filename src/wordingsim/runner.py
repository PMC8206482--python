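"""Orchestration of the simulation studies over the factorial design.

One *replicate* of a study covers a (N, test length) cell: a single
uncontaminated matrix is generated, the reference one-factor model is fitted
to it (its EAP scores are both the recovery reference and the IVD trait
classifier), and the same matrix is then contaminated at every requested
PERC.WE level and refitted with the 1F and RIIFA models.  Seeding is
counter-based (master seed + study/cell/replicate labels) so any cell can be
reproduced in isolation and results do not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assess import RecoveryRecord, loading_error, mixed_anova_eta, score_recovery, wording_score_diagnostics
from .contamination import contaminate
from .datagen import (
    DEFAULT_INCONSISTENT_FRAC,
    DesignCell,
    generate_sample,
    make_rng,
)
from .sem import WordingFactorModel, factor_scores

logger = logging.getLogger(__name__)

_EFFECT_CODE = {"carelessness": 1, "ivd": 2, "acquiescence": 3}


@dataclass
class StudyConfig:
    """Factorial design of one study (defaults are the full study conditions)."""

    effect_type: str
    perc_levels: tuple = (0, 10, 20, 30, 40, 50)
    n_levels: tuple = (200, 500, 1000)
    length_levels: tuple = (12, 24, 60)
    reps: int = 100
    inconsistent_frac: float = DEFAULT_INCONSISTENT_FRAC
    master_seed: int = 0
    custom: bool = False

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not (self.perc_levels and self.n_levels and self.length_levels):
            raise ValueError("factor levels must be nonempty")


def _fit_models(data, pop_spec, uncont_scores, cell) -> list[RecoveryRecord]:
    """Fit 1F and RIIFA to one (contaminated) matrix and assess both."""
    records = []
    pw_mask = pop_spec.loadings >= 0
    for kind, label in (("onefactor", "1f"), ("riifa", "riifa")):
        fit = WordingFactorModel.from_sample(data, kind).fit(compute_scores=False)
        rec = RecoveryRecord(cell=cell, model=label, converged=fit.converged)
        if fit.converged:
            sf, wf = factor_scores(data, fit)
            rec.r_total, rec.r_consistent, rec.r_inconsistent = score_recovery(
                uncont_scores, sf, data.inconsistent_flags
            )
            rec.mbe_pw, rec.mae_pw, rec.mbe_nw, rec.mae_nw = loading_error(
                fit.loadings_hat, pop_spec.loadings, pw_mask
            )
            rec.beta_sf, rec.beta_wf, rec.r2 = fit.beta_sf, fit.beta_wf, fit.r2
            rec.cfi, rec.rmsea, rec.omega = fit.cfi, fit.rmsea, fit.omega_hat
            if wf is not None:
                rec.r_wf_uncont = wording_score_diagnostics(
                    uncont_scores, wf, data.inconsistent_flags
                )["overall"]
        records.append(rec)
    return records


def run_replicate(
    effect_type: str,
    n: int,
    test_length: int,
    replicate_id: int,
    perc_levels,
    master_seed: int = 0,
    inconsistent_frac: float = DEFAULT_INCONSISTENT_FRAC,
    custom: bool = False,
) -> list[RecoveryRecord]:
    """All records for one uncontaminated matrix across its PERC.WE levels."""
    code = _EFFECT_CODE[effect_type]
    base = (master_seed, code, n, test_length, replicate_id)
    clean_cell = DesignCell("none", 0, n, test_length, replicate_id, custom=True)
    pop_spec, clean = generate_sample(
        clean_cell,
        spec_seed=_seed_from(base + (1,)),
        sample_seed=_seed_from(base + (2,)),
        inconsistent_frac=inconsistent_frac,
    )
    return _run_from_clean(
        effect_type, pop_spec, clean, n, test_length, replicate_id, perc_levels, master_seed, custom
    )


def _run_from_clean(
    effect_type, pop_spec, clean, n, test_length, replicate_id, perc_levels, master_seed, custom
):
    code = _EFFECT_CODE[effect_type]
    ref_fit = WordingFactorModel.from_sample(clean, "onefactor").fit(compute_scores=False)
    uncont_scores, _ = factor_scores(clean, ref_fit)
    records: list[RecoveryRecord] = []
    for perc in perc_levels:
        cell = DesignCell(effect_type, perc, n, test_length, replicate_id, custom=custom)
        if perc == 0:
            contaminated = clean
        else:
            rng = make_rng(master_seed, code, n, test_length, replicate_id, 3, perc)
            contaminated, _ = contaminate(
                clean, effect_type, perc, rng,
                trait_scores=uncont_scores if effect_type == "ivd" else None,
            )
        try:
            records.extend(_fit_models(contaminated, pop_spec, uncont_scores, cell))
        except Exception:  # never abort a study on one bad replicate
            logger.exception("replicate failed: %s", cell)
            for label in ("1f", "riifa"):
                records.append(RecoveryRecord(cell=cell, model=label, converged=False))
    return records


_HASHABLE_SEED = 2**31


def _seed_from(parts) -> int:
    # stable FNV-style integer hash (python's hash() is salted across processes)
    h = 1469598103934665603
    for p in parts:
        h = ((h ^ (int(p) % (2**32))) * 1099511628211) % (2**64)
    return h % _HASHABLE_SEED


def run_study(config: StudyConfig, progress: bool = False) -> dict:
    """Run the full factorial study; returns tidy tables.

    Output dict keys: ``replicates`` (one row per model x cell x replicate),
    ``cell_summary`` (per-cell means over converged replicates),
    ``convergence`` (rates per cell), ``anova`` (split-plot effect sizes on
    total recovery, 20%+ conditions).
    """
    records: list[RecoveryRecord] = []
    code = _EFFECT_CODE[config.effect_type]
    for n in config.n_levels:
        for k in config.length_levels:
            for rep in range(config.reps):
                spec_seed = _seed_from((config.master_seed, code, n, k, rep, 1))
                sample_seed = _seed_from((config.master_seed, code, n, k, rep, 2))
                clean_cell = DesignCell("none", 0, n, k, rep, custom=True)
                pop_spec, clean = generate_sample(
                    clean_cell, spec_seed, sample_seed, config.inconsistent_frac
                )
                records.extend(
                    _run_from_clean(
                        config.effect_type, pop_spec, clean, n, k, rep,
                        config.perc_levels, config.master_seed, config.custom,
                    )
                )
            if progress:
                logger.info("finished N=%d, k=%d", n, k)
    table = pd.DataFrame([r.to_dict() for r in records])
    return {
        "replicates": table,
        "cell_summary": summarize_cells(table),
        "convergence": convergence_table(table),
        "anova": study_anova(table),
    }


def summarize_cells(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell means of all assessment criteria over converged replicates."""
    conv = table[table.converged]
    keys = ["effect", "perc_we", "n", "test_length", "model"]
    return conv.groupby(keys, as_index=False).agg(
        reps=("replicate", "size"),
        r_total=("r_total", "mean"),
        r_consistent=("r_consistent", "mean"),
        r_inconsistent=("r_inconsistent", "mean"),
        mbe_pw=("mbe_pw", "mean"),
        mbe_nw=("mbe_nw", "mean"),
        mae_pw=("mae_pw", "mean"),
        mae_nw=("mae_nw", "mean"),
        beta_sf=("beta_sf", "mean"),
        beta_wf=("beta_wf", "mean"),
        r2=("r2", "mean"),
        cfi=("cfi", "mean"),
        rmsea=("rmsea", "mean"),
    )


def convergence_table(table: pd.DataFrame) -> pd.DataFrame:
    keys = ["effect", "perc_we", "n", "test_length", "model"]
    return table.groupby(keys, as_index=False).agg(
        reps=("replicate", "size"), convergence_rate=("converged", "mean")
    )


def study_anova(table: pd.DataFrame, dv: str = "r_total", min_perc: int = 20) -> pd.DataFrame:
    """Mixed-ANOVA effect sizes; returns an empty frame if the design is degenerate."""
    try:
        return mixed_anova_eta(table, dv=dv, min_perc=min_perc)
    except Exception:
        logger.exception("mixed ANOVA failed")
        return pd.DataFrame(columns=["effect", "ss", "df", "F", "eta_p_sq"])


def save_study(results: dict, outdir: str | Path, config: StudyConfig | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("replicates", "cell_summary", "convergence", "anova"):
        results[name].to_csv(outdir / f"{name}.csv", index=False)
    if config is not None:
        import yaml

        cfg = {
            "effect_type": config.effect_type,
            "perc_levels": list(config.perc_levels),
            "n_levels": list(config.n_levels),
            "length_levels": list(config.length_levels),
            "reps": config.reps,
            "inconsistent_frac": config.inconsistent_frac,
            "master_seed": config.master_seed,
        }
        (outdir / "config.yaml").write_text(yaml.safe_dump(cfg))
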