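"""Injection of wording effects into uncontaminated response matrices.

Three mechanisms are modeled, all applied only to the pre-flagged 40% of
"inconsistent" respondents and touching round(perc/100 * k) items each:

* carelessness - NW-item responses are reversed (1<->4, 2<->3), as if the
  respondent answered every item as positively worded;
* item verification difficulty (IVD) - reversal keyed on the respondent's
  uncontaminated trait estimate: PW items reversed for below-zero scorers, NW
  items for the rest;
* acquiescence - upward category switching (1->3, 2->3 or 4, 3->4; 4 fixed)
  with selection weights 0.50/0.33/0.17 for categories 1/2/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datagen import SampleData, round_half_up

ACQ_SWITCH_PROBS = {1: 0.50, 2: 0.33, 3: 0.17}


class InfeasibleContaminationError(ValueError):
    """Target item count exceeds the set of items eligible for the effect."""


@dataclass(frozen=True)
class ContaminationSpec:
    effect_type: str
    perc_we: float
    k: int
    switch_probs: dict | None = None

    def __post_init__(self) -> None:
        if self.effect_type not in ("carelessness", "ivd", "acquiescence"):
            raise ValueError(f"unknown effect type {self.effect_type!r}")
        if self.effect_type == "acquiescence":
            if self.switch_probs is None:
                object.__setattr__(self, "switch_probs", dict(ACQ_SWITCH_PROBS))
        elif self.switch_probs is not None:
            raise ValueError("switch_probs only apply to acquiescence")

    @property
    def target_item_count(self) -> int:
        """round(perc/100 * k), at least 1 whenever perc > 0."""
        if self.perc_we <= 0:
            return 0
        return max(1, round_half_up(self.perc_we / 100.0 * self.k))


def reverse_categories(responses: np.ndarray, positions) -> np.ndarray:
    """Map categories 1<->4 and 2<->3 at ``positions``; others unchanged."""
    out = np.asarray(responses).copy()
    if out.size and (out.min() < 1 or out.max() > 4):
        raise ValueError("categories must lie in 1..4")
    idx = np.asarray(positions, dtype=int)
    if idx.size:
        out[idx] = 5 - out[idx]
    return out


@dataclass
class ChangeLog:
    """Record of every modified cell (respondent, item, old, new)."""

    respondent: list[int] = field(default_factory=list)
    item: list[int] = field(default_factory=list)
    old: list[int] = field(default_factory=list)
    new: list[int] = field(default_factory=list)
    exhausted: list[int] = field(default_factory=list)

    def add(self, resp: int, items: np.ndarray, old: np.ndarray, new: np.ndarray) -> None:
        self.respondent.extend([resp] * len(items))
        self.item.extend(int(i) for i in items)
        self.old.extend(int(v) for v in old)
        self.new.extend(int(v) for v in new)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"respondent": self.respondent, "item": self.item, "old": self.old, "new": self.new}
        )


def _reversal_effect(
    data: SampleData,
    spec: ContaminationSpec,
    eligible_per_respondent,
    rng: np.random.Generator,
) -> tuple[SampleData, ChangeLog]:
    out = data.copy()
    log = ChangeLog()
    m = spec.target_item_count
    if m == 0:
        return out, log
    for r in np.flatnonzero(data.inconsistent_flags):
        eligible = eligible_per_respondent(r)
        if m > eligible.size:
            raise InfeasibleContaminationError(
                f"respondent {r}: {m} items requested but only {eligible.size} eligible"
            )
        chosen = rng.choice(eligible, size=m, replace=False)
        old = out.responses[r, chosen].copy()
        out.responses[r, chosen] = 5 - old
        log.add(int(r), chosen, old, out.responses[r, chosen])
    return out, log


def apply_carelessness(
    data: SampleData, spec: ContaminationSpec, rng: np.random.Generator
) -> tuple[SampleData, ChangeLog]:
    """Reverse a random subset of NW items for each inconsistent respondent."""
    if spec.effect_type != "carelessness":
        raise ValueError("spec.effect_type must be 'carelessness'")
    nw = np.flatnonzero(np.asarray(data.item_polarity) == "NW")
    return _reversal_effect(data, spec, lambda r: nw, rng)


def apply_ivd(
    data: SampleData,
    spec: ContaminationSpec,
    trait_scores: np.ndarray,
    rng: np.random.Generator,
) -> tuple[SampleData, ChangeLog]:
    """Trait-conditional reversal: PW items if score < 0, NW items otherwise.

    ``trait_scores`` are the respondents' uncontaminated substantive factor
    scores (one-factor model fitted to the clean matrix); a score of exactly 0
    takes the high-trait branch.
    """
    if spec.effect_type != "ivd":
        raise ValueError("spec.effect_type must be 'ivd'")
    trait_scores = np.asarray(trait_scores, dtype=float)
    if trait_scores.shape != (data.n,):
        raise ValueError("trait_scores length mismatch")
    polarity = np.asarray(data.item_polarity)
    pw = np.flatnonzero(polarity == "PW")
    nw = np.flatnonzero(polarity == "NW")
    return _reversal_effect(
        data, spec, lambda r: pw if trait_scores[r] < 0 else nw, rng
    )


def apply_acquiescence(
    data: SampleData, spec: ContaminationSpec, rng: np.random.Generator
) -> tuple[SampleData, ChangeLog]:
    """Probabilistic upward switching for inconsistent respondents.

    Items are drawn without replacement with weights given by their current
    category (4s are ineligible; a changed item becomes ineligible) until the
    target count is reached or no eligible item remains.  Since unchanged
    items keep their original category, the successive weighted draws are
    realized exactly by exponential sort keys (Efraimidis-Spirakis).
    """
    if spec.effect_type != "acquiescence":
        raise ValueError("spec.effect_type must be 'acquiescence'")
    out = data.copy()
    log = ChangeLog()
    m = spec.target_item_count
    if m == 0:
        return out, log
    probs = spec.switch_probs
    weight_of = np.array([0.0, probs[1], probs[2], probs[3], 0.0])  # index = category
    for r in np.flatnonzero(data.inconsistent_flags):
        row = out.responses[r]
        w = weight_of[row]
        eligible = np.flatnonzero(w > 0)
        if eligible.size == 0:
            log.exhausted.append(int(r))
            continue
        keys = rng.exponential(size=eligible.size) / w[eligible]
        take = min(m, eligible.size)
        chosen = eligible[np.argsort(keys)[:take]]
        if take < m:
            log.exhausted.append(int(r))
        old = row[chosen].copy()
        new = old.copy()
        new[old == 1] = 3
        new[old == 3] = 4
        twos = old == 2
        if np.any(twos):
            new[twos] = rng.choice([3, 4], size=int(twos.sum()))
        row[chosen] = new
        log.add(int(r), chosen, old, new)
    return out, log


def contaminate(
    data: SampleData,
    effect_type: str,
    perc_we: float,
    rng: np.random.Generator,
    trait_scores: np.ndarray | None = None,
) -> tuple[SampleData, ChangeLog]:
    """Dispatch to the requested wording-effect mechanism."""
    spec = ContaminationSpec(effect_type=effect_type, perc_we=perc_we, k=data.k)
    if effect_type == "carelessness":
        return apply_carelessness(data, spec, rng)
    if effect_type == "ivd":
        if trait_scores is None:
            raise ValueError("IVD requires uncontaminated trait scores")
        return apply_ivd(data, spec, trait_scores, rng)
    return apply_acquiescence(data, spec, rng)
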