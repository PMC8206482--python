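"""Generation of uncontaminated ordinal questionnaire data.

The generating model is a unidimensional common factor model for a balanced
scale (half positively worded, half negatively worded items) plus a single
continuous criterion variable loading 1.0 on its own factor, with the two
factors correlated 0.50.  Item loadings are drawn from U(0.60, 0.80) (mean
0.70) and half receive a negative sign.  Continuous responses are produced by
Cholesky factorization of the model-implied population correlation matrix and
then cut into four ordered categories at thresholds (-1.5, 0, 1.5), which give
symmetric marginal distributions; the criterion stays continuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_THRESHOLDS = (-1.5, 0.0, 1.5)
DEFAULT_FACTOR_CORR = 0.50
DEFAULT_INCONSISTENT_FRAC = 0.40

#: factorial levels of the three simulation studies
PERC_WE_LEVELS = (0, 10, 20, 30, 40, 50)
N_LEVELS = (200, 500, 1000)
TEST_LENGTH_LEVELS = (12, 24, 60)
EFFECT_TYPES = ("none", "carelessness", "ivd", "acquiescence")


class BalancedScaleError(ValueError):
    """Raised when the requested test cannot be split into equal PW/NW halves."""


class GenerationError(RuntimeError):
    """Raised when the population model is numerically inadmissible."""


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going away from zero (0.5 -> 1)."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class PopulationSpec:
    """Generating model for one replicate.

    ``loadings`` are the signed substantive-factor loadings (NW items carry the
    negative sign); ``criterion_loading`` is the fixed loading of the observed
    criterion on its own factor and ``factor_corr`` the substantive-criterion
    factor correlation.
    """

    n_items: int
    loadings: np.ndarray
    criterion_loading: float = 1.0
    factor_corr: float = DEFAULT_FACTOR_CORR
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    n_categories: int = 4

    def __post_init__(self) -> None:
        lam = np.asarray(self.loadings, dtype=float)
        object.__setattr__(self, "loadings", lam)
        if lam.shape != (self.n_items,):
            raise ValueError("loadings must have length n_items")
        if np.any(np.abs(lam) < 0.60 - 1e-12) or np.any(np.abs(lam) > 0.80 + 1e-12):
            raise ValueError("|loading| outside [0.60, 0.80]")
        if int(np.sum(lam < 0)) != self.n_items // 2:
            raise ValueError("exactly floor(k/2) loadings must be negative")
        if not np.all(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if not -1 < self.factor_corr < 1:
            raise ValueError("factor_corr must lie in (-1, 1)")

    @property
    def item_polarity(self) -> np.ndarray:
        """'PW' for positive loadings, 'NW' for negative ones."""
        return np.where(self.loadings >= 0, "PW", "NW")


@dataclass
class SampleData:
    """One simulated dataset: ordinal item responses plus continuous criterion.

    ``inconsistent_flags`` marks the respondents pre-selected to misrespond in
    the contamination step (40% of the sample by default); the uncontaminated
    matrix itself is identical for flagged and unflagged respondents.
    """

    responses: np.ndarray
    criterion: np.ndarray
    item_polarity: np.ndarray
    inconsistent_flags: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.int64)
        self.criterion = np.asarray(self.criterion, dtype=float)
        self.inconsistent_flags = np.asarray(self.inconsistent_flags, dtype=bool)
        n, k = self.responses.shape
        if self.criterion.shape != (n,) or self.inconsistent_flags.shape != (n,):
            raise ValueError("criterion / flags length mismatch")
        if len(self.item_polarity) != k:
            raise ValueError("item_polarity length mismatch")
        if self.responses.min() < 1 or self.responses.max() > 4:
            raise ValueError("responses outside category bounds 1..4")

    @property
    def n(self) -> int:
        return self.responses.shape[0]

    @property
    def k(self) -> int:
        return self.responses.shape[1]

    def copy(self) -> "SampleData":
        return SampleData(
            self.responses.copy(),
            self.criterion.copy(),
            np.array(self.item_polarity),
            self.inconsistent_flags.copy(),
            self.seed,
        )


@dataclass(frozen=True)
class DesignCell:
    """One cell of the PERC.WE x N x T.LENG factorial design."""

    effect_type: str
    perc_we: int
    n: int
    test_length: int
    replicate_id: int = 0
    custom: bool = False

    def __post_init__(self) -> None:
        if self.effect_type not in EFFECT_TYPES:
            raise ValueError(f"unknown effect type {self.effect_type!r}")
        if not self.custom:
            if self.perc_we not in PERC_WE_LEVELS:
                raise ValueError(f"perc_we {self.perc_we} not a design level")
            if self.n not in N_LEVELS:
                raise ValueError(f"n {self.n} not a design level")
            if self.test_length not in TEST_LENGTH_LEVELS:
                raise ValueError(f"test_length {self.test_length} not a design level")


def draw_loadings(k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw k signed loadings: |lambda| ~ U(0.60, 0.80), k/2 random negatives."""
    if k % 2 != 0 or k < 2:
        raise BalancedScaleError(f"test length must be even and >= 2, got {k}")
    lam = rng.uniform(0.60, 0.80, size=k)
    neg = rng.choice(k, size=k // 2, replace=False)
    lam[neg] *= -1.0
    return lam


def build_population_matrix(spec: PopulationSpec) -> np.ndarray:
    """Model-implied population correlation matrix, items first, criterion last.

    Off-diagonal entries are Lambda Phi Lambda' for the two-factor measurement
    model (substantive + criterion factor); unities are inserted on the
    diagonal to raise the reduced matrix to full rank.
    """
    k = spec.n_items
    lam = np.zeros((k + 1, 2))
    lam[:k, 0] = spec.loadings
    lam[k, 1] = spec.criterion_loading
    phi = np.array([[1.0, spec.factor_corr], [spec.factor_corr, 1.0]])
    r = lam @ phi @ lam.T
    np.fill_diagonal(r, 1.0)
    eigmin = np.linalg.eigvalsh(r)[0]
    if eigmin <= 0:
        raise GenerationError(
            f"population correlation matrix not positive definite (min eigenvalue {eigmin:.3e})"
        )
    return r


def simulate_continuous(pop_matrix: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n multivariate-normal rows with correlation ``pop_matrix`` (X = Z U)."""
    try:
        u = np.linalg.cholesky(pop_matrix).T  # upper triangular, R = U'U
    except np.linalg.LinAlgError as err:
        raise GenerationError("Cholesky factorization of the population matrix failed") from err
    z = rng.standard_normal(size=(n, pop_matrix.shape[0]))
    return z @ u


def categorize(x: np.ndarray, thresholds=DEFAULT_THRESHOLDS) -> np.ndarray:
    """Cut continuous scores into categories 1..len(thresholds)+1.

    A value equal to a threshold goes to the lower category (x <= tau), a fixed
    convention for determinism; the event has probability zero in simulation.
    """
    tau = np.asarray(thresholds, dtype=float)
    if not np.all(np.diff(tau) > 0):
        raise ValueError("thresholds must be strictly increasing")
    return 1 + np.searchsorted(tau, np.asarray(x), side="left")


def make_rng(*entropy: int) -> np.random.Generator:
    """Counter-based substream: same entropy tuple -> same stream, any order."""
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def generate_sample(
    cell: DesignCell,
    spec_seed: int,
    sample_seed: int,
    inconsistent_frac: float = DEFAULT_INCONSISTENT_FRAC,
) -> tuple[PopulationSpec, SampleData]:
    """Run the full uncontaminated pipeline for one design cell.

    Loadings are drawn once per replicate (``spec_seed``); the response matrix
    and the inconsistent-respondent flags use ``sample_seed``.  The same
    uncontaminated matrix and flags are reused across PERC.WE levels.
    """
    k, n = cell.test_length, cell.n
    spec_rng = make_rng(spec_seed)
    spec = PopulationSpec(n_items=k, loadings=draw_loadings(k, spec_rng))
    rng = make_rng(sample_seed)
    pop = build_population_matrix(spec)
    x = simulate_continuous(pop, n, rng)
    responses = categorize(x[:, :k], spec.thresholds)
    criterion = x[:, k]
    n_flag = round_half_up(inconsistent_frac * n)
    flags = np.zeros(n, dtype=bool)
    flags[rng.choice(n, size=n_flag, replace=False)] = True
    data = SampleData(responses, criterion, spec.item_polarity, flags, seed=sample_seed)
    return spec, data
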