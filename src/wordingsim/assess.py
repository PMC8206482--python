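"""Assessment criteria: loading recovery, score recovery, effect sizes.

Loading recovery uses the mean (signed) bias error and the mean absolute
error of estimated vs generating substantive loadings, separately for
positively and negatively worded items.  Score recovery is the Pearson
correlation between person scores estimated on the clean matrix and on the
contaminated one, over all respondents and the consistent / inconsistent
subsets.  Model comparisons use a split-plot (mixed) ANOVA with the model as
the repeated factor, summarized by partial eta squared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .datagen import DesignCell


@dataclass
class RecoveryRecord:
    """Per-replicate, per-model assessment summary (one tidy row)."""

    cell: DesignCell
    model: str
    converged: bool
    r_total: float = np.nan
    r_consistent: float = np.nan
    r_inconsistent: float = np.nan
    mbe_pw: float = np.nan
    mbe_nw: float = np.nan
    mae_pw: float = np.nan
    mae_nw: float = np.nan
    beta_sf: float = np.nan
    beta_wf: float = np.nan
    r2: float = np.nan
    cfi: float = np.nan
    rmsea: float = np.nan
    omega: float = np.nan
    r_wf_uncont: float = np.nan

    def to_dict(self) -> dict:
        d = {
            "effect": self.cell.effect_type,
            "perc_we": self.cell.perc_we,
            "n": self.cell.n,
            "test_length": self.cell.test_length,
            "replicate": self.cell.replicate_id,
            "model": self.model,
            "converged": self.converged,
        }
        for f in (
            "r_total",
            "r_consistent",
            "r_inconsistent",
            "mbe_pw",
            "mbe_nw",
            "mae_pw",
            "mae_nw",
            "beta_sf",
            "beta_wf",
            "r2",
            "cfi",
            "rmsea",
            "omega",
            "r_wf_uncont",
        ):
            d[f] = getattr(self, f)
        return d


def loading_error(est: np.ndarray, true: np.ndarray, polarity_mask: np.ndarray):
    """MBE and MAE of estimated vs generating loadings, per polarity group.

    ``polarity_mask`` is True for PW items.  Returns
    ``(mbe_pw, mae_pw, mbe_nw, mae_nw)``; an empty group yields NaNs.
    """
    est = np.asarray(est, dtype=float)
    true = np.asarray(true, dtype=float)
    mask = np.asarray(polarity_mask, dtype=bool)
    if est.shape != true.shape or est.shape != mask.shape:
        raise ValueError("length mismatch")
    out = []
    for grp in (mask, ~mask):
        if grp.sum() == 0:
            out += [np.nan, np.nan]
            continue
        diff = est[grp] - true[grp]
        out += [float(diff.mean()), float(np.abs(diff).mean())]
    return tuple(out)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3 or np.std(a) < 1e-12 or np.std(b) < 1e-12:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def score_recovery(uncont: np.ndarray, cont: np.ndarray, flags: np.ndarray):
    """Recovery correlations: total / consistent-only / inconsistent-only."""
    uncont = np.asarray(uncont, dtype=float)
    cont = np.asarray(cont, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if not (uncont.shape == cont.shape == flags.shape):
        raise ValueError("length mismatch")
    return (
        _safe_corr(uncont, cont),
        _safe_corr(uncont[~flags], cont[~flags]),
        _safe_corr(uncont[flags], cont[flags]),
    )


def wording_score_diagnostics(uncont_sf: np.ndarray, scores_wf: np.ndarray, flags: np.ndarray):
    """Correlation of wording scores with clean substantive scores, by subgroup."""
    flags = np.asarray(flags, dtype=bool)
    return {
        "overall": _safe_corr(uncont_sf, scores_wf),
        "consistent": _safe_corr(uncont_sf[~flags], scores_wf[~flags]),
        "inconsistent": _safe_corr(uncont_sf[flags], scores_wf[flags]),
    }


def mixed_anova_eta(table: pd.DataFrame, dv: str = "r_total", min_perc: int = 20) -> pd.DataFrame:
    """Partial eta squared for the split-plot ANOVA on model recovery.

    The within factor is the model (1F vs RIIFA, repeated on each replicate);
    between factors are PERC.WE, N and test length.  Replicates missing either
    model (non-convergence) are dropped pairwise; the low-wording-effect
    conditions below ``min_perc`` are excluded.  With two within levels the
    within stratum reduces to an ANOVA on the per-replicate model difference:
    Type-III SS of the intercept is the model main effect, factor terms are
    the model x between interactions, the residual is the within error.
    """
    df = table[(table.perc_we >= min_perc) & table.converged].copy()
    wide = df.pivot_table(
        index=["effect", "perc_we", "n", "test_length", "replicate"],
        columns="model",
        values=dv,
    ).dropna()
    if wide.shape[1] != 2:
        raise ValueError("need exactly two models for the repeated factor")
    wide = wide.reset_index()
    m1, m2 = sorted(c for c in wide.columns if c in ("1f", "riifa"))
    wide["d"] = wide[m1] - wide[m2]
    factors = [f for f in ("perc_we", "n", "test_length") if wide[f].nunique() > 1]
    rhs = " * ".join(f"C({f}, Sum)" for f in factors) if factors else "1"
    model = ols(f"d ~ {rhs}", data=wide).fit()
    aov = sm.stats.anova_lm(model, typ=3)
    sse = aov.loc["Residual", "sum_sq"]
    rows = []
    for name, row in aov.iterrows():
        if name == "Residual":
            continue
        label = "model" if name == "Intercept" else "model x " + (
            name.replace("C(perc_we, Sum)", "perc_we")
            .replace("C(n, Sum)", "n")
            .replace("C(test_length, Sum)", "test_length")
            .replace(":", " x ")
        )
        ss = row["sum_sq"]
        rows.append(
            {
                "effect": label,
                "ss": ss,
                "df": row["df"],
                "F": row["F"],
                "eta_p_sq": ss / (ss + sse) if ss + sse > 0 else 0.0,
            }
        )
    rows.append({"effect": "within error", "ss": sse, "df": aov.loc["Residual", "df"], "F": np.nan, "eta_p_sq": np.nan})
    return pd.DataFrame(rows)
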