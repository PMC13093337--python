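"""Four-model drug-combination synergy evaluation.

Per-group treatment effects are estimated against the untreated injury
reference with seeded permutation significance, then judged under combination
subthresholding, highest single agent (HSA), response additivity, and Bliss
independence.  All comparisons use strict inequalities (ties are not synergy);
a non-positive monotherapy fractional effect flags the Bliss verdict as
"NA-conditions-unmet" while still reporting its direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REFERENCE = "OGD"
BASELINE = "control"
COMBO = "AzEpo"
MONO_A = "Az"
MONO_B = "Epo"

SYNERGY = "synergy"
NO_SYNERGY = "no-synergy"
OK = "ok"
NA = "NA-conditions-unmet"


@dataclass
class EffectEstimate:
    group: str
    mean: float
    delta: float  # mean(reference) - mean(group); positive = protection
    fractional_effect: float
    p_value: float
    n: int


@dataclass
class SynergyVerdict:
    model: str
    verdict: str
    applicability: str = OK
    expected: float | None = None
    observed: float | None = None
    assay: str = ""
    region: str = ""


def _permutation_p(x: np.ndarray, ref: np.ndarray, n_perm: int, rng) -> float:
    """Two-sided permutation p-value for a difference in group means."""
    obs = abs(x.mean() - ref.mean())
    pooled = np.concatenate([x, ref])
    nx = len(x)
    idx = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    perm = pooled[idx]
    diffs = np.abs(perm[:, :nx].mean(axis=1) - perm[:, nx:].mean(axis=1))
    return float((1 + np.sum(diffs >= obs - 1e-12)) / (n_perm + 1))


def effect_estimates(outcomes: pd.DataFrame, reference: str = REFERENCE,
                     baseline: str = BASELINE, n_perm: int = 10_000,
                     seed: int = 0, value_col: str = "value") -> dict:
    """Per-group effect estimates from a per-slice outcome table.

    delta_X = mean(reference) - mean(X); fractional effect
    f_X = delta_X / (mean(reference) - mean(baseline)).  Significance is a
    two-sided seeded label-permutation test of group X against the reference.
    """
    groups = {g: sub[value_col].to_numpy(dtype=float)
              for g, sub in outcomes.groupby("group")}
    for required in (reference, baseline):
        if required not in groups:
            raise ValueError(f"outcomes missing group {required!r}")
    ref = groups[reference]
    injury = ref.mean() - groups[baseline].mean()
    if injury == 0:
        raise ValueError("no injury signal: mean(reference) == mean(baseline)")
    rng = np.random.default_rng(seed)
    out = {}
    for g in sorted(groups):
        x = groups[g]
        delta = float(ref.mean() - x.mean())
        p = 1.0 if g == reference else _permutation_p(x, ref, n_perm, rng)
        out[g] = EffectEstimate(group=g, mean=float(x.mean()), delta=delta,
                                fractional_effect=delta / injury, p_value=p,
                                n=len(x))
    return out


def _require(estimates: dict, *groups: str) -> None:
    missing = [g for g in groups if g not in estimates]
    if missing:
        raise ValueError(f"estimates missing groups: {missing}")


def subthreshold_synergy(estimates: dict, alpha: float = 0.05) -> SynergyVerdict:
    """Synergy iff neither monotherapy is significant but the combination is
    (and protective)."""
    _require(estimates, MONO_A, MONO_B, COMBO)
    a, b, c = estimates[MONO_A], estimates[MONO_B], estimates[COMBO]
    hit = (a.p_value >= alpha and b.p_value >= alpha and c.p_value < alpha
           and c.delta > 0)
    return SynergyVerdict("subthreshold", SYNERGY if hit else NO_SYNERGY,
                          observed=c.delta)


def hsa_synergy(estimates: dict) -> SynergyVerdict:
    """Synergy iff the combination delta strictly exceeds the best mono delta."""
    _require(estimates, MONO_A, MONO_B, COMBO)
    best = max(estimates[MONO_A].delta, estimates[MONO_B].delta)
    obs = estimates[COMBO].delta
    return SynergyVerdict("HSA", SYNERGY if obs > best else NO_SYNERGY,
                          expected=best, observed=obs)


def additivity_synergy(estimates: dict) -> SynergyVerdict:
    """Synergy iff the combination delta strictly exceeds the sum of monos."""
    _require(estimates, MONO_A, MONO_B, COMBO)
    expected = estimates[MONO_A].delta + estimates[MONO_B].delta
    obs = estimates[COMBO].delta
    return SynergyVerdict("additivity", SYNERGY if obs > expected else NO_SYNERGY,
                          expected=expected, observed=obs)


def bliss_expected(f_a: float, f_b: float) -> float:
    """Expected combined fractional effect under independent drug action."""
    return f_a + f_b - f_a * f_b


def bliss_synergy(estimates: dict) -> SynergyVerdict:
    """Bliss independence verdict with an applicability flag.

    Expected f = f_A + f_B - f_A*f_B.  When either monotherapy fractional
    effect is <= 0 the independence assumption is unmet: the verdict direction
    is still reported but flagged NA-conditions-unmet.
    """
    _require(estimates, MONO_A, MONO_B, COMBO)
    f_a = estimates[MONO_A].fractional_effect
    f_b = estimates[MONO_B].fractional_effect
    expected = bliss_expected(f_a, f_b)
    obs = estimates[COMBO].fractional_effect
    applicability = NA if (f_a <= 0 or f_b <= 0) else OK
    return SynergyVerdict("bliss", SYNERGY if obs > expected else NO_SYNERGY,
                          applicability=applicability, expected=expected,
                          observed=obs)


ALL_MODELS = (subthreshold_synergy, hsa_synergy, additivity_synergy,
              bliss_synergy)


def evaluate_all(estimates: dict, alpha: float = 0.05) -> list[SynergyVerdict]:
    out = [subthreshold_synergy(estimates, alpha=alpha), hsa_synergy(estimates),
           additivity_synergy(estimates), bliss_synergy(estimates)]
    return out


def synergy_matrix(outcomes: pd.DataFrame, alpha: float = 0.05,
                   n_perm: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Verdict grid across every (assay, region): one row per model per cell."""
    rows = []
    for (assay, region), sub in outcomes.groupby(["assay", "region"]):
        est = effect_estimates(sub, n_perm=n_perm, seed=seed)
        for v in evaluate_all(est, alpha=alpha):
            rows.append({"assay": assay, "region": region, "model": v.model,
                         "verdict": v.verdict, "applicability": v.applicability,
                         "expected": v.expected, "observed": v.observed,
                         "p_Az": est[MONO_A].p_value,
                         "p_Epo": est[MONO_B].p_value,
                         "p_AzEpo": est[COMBO].p_value})
    return pd.DataFrame(rows)
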