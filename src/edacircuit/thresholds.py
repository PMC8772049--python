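"""Closed-form extinction/persistence thresholds and regime classification.

The stochastic theory yields sufficient conditions on the noise under which
the intermediate species y(t) is driven to zero (the reaction ends, the
ThT fluorescence saturates) or stays persistent in time average (the
reaction continues at a dynamic equilibrium).  Everything is expressed in
terms of the reduced-model coefficients, the region bound
K = k2*(x0-c0)/(2*k_minus1-k2), and two effective noise intensities:

    sigma'^2  = sigma^2 + int_Y gamma^2(u)/(1+delta)^2 lambda(du)   (extinction)
    sigma''^2 = sigma^2 + int_Y gamma^2(u)/(1-delta)^2 lambda(du)   (persistence)

Extinction holds if either

    (a) sigma'^2 > c1^2 / (2*b2), with log-growth bound c1^2/(2*sigma'^2) + b2, or
    (b) sigma'^2 <= c1/K and (c1/b2)*K - (sigma'^2/(2*b2))*K^2 < 1,
        with bound b2 * [-1 + (c1/b2)*K - (sigma'^2/(2*b2))*K^2];

persistence is sufficient when R0* = R0 - (sigma''^2/(2*b2))*K^2 > 1.  The
source publication never defines R0 itself; this module adopts
R0 := (c1/b2)*K by structural analogy with condition (b) (the persistence
index is its sigma''-penalised counterpart).  The adopted definition is
overridable and flagged in every report.

The publication's own printed check values for its three simulation cases
could not be reproduced from its printed parameters under any reading; this
module therefore evaluates the formulas as displayed, reports margins for
every inequality, and attaches discrepancy warnings instead of matching
those numbers.  Empirical truth is deferred to simulation (see
:mod:`edacircuit.diagnostics`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List

from .model import (
    DegenerateParameterError,
    DerivedCoefficients,
    InitialConditions,
    RateConstants,
    ValidationError,
)
from .sde import NoiseSpec

__all__ = [
    "ThresholdReport",
    "sigma_prime_sq",
    "sigma_dprime_sq",
    "check_assumption1",
    "extinction_condition_a",
    "extinction_condition_b",
    "lyapunov_growth_bound",
    "r0",
    "r0_star",
    "persistence_lower_bound",
    "regime_from_flags",
    "classify_regime",
    "REGIMES",
]

REGIMES = ("end_a", "end_b", "persistent", "indeterminate", "conflict")

R0_DEFINITION_NOTE = (
    "R0 is not defined in the source publication; this report uses the "
    "adopted definition R0 := (c1/b2)*K (overridable via r0_override)"
)
PRINTED_CLAIMS_NOTE = (
    "the source publication's printed numerical check values for its "
    "simulation cases are not reproducible from its printed parameters; "
    "all quantities here are recomputed from the displayed formulas"
)


def sigma_prime_sq(noise: NoiseSpec) -> float:
    """Effective extinction noise intensity
    sigma'^2 = sigma^2 + int_Y gamma^2(u)/(1+delta)^2 lambda(du)."""
    return noise.sigma**2 + noise.int_gamma_sq / (1.0 + noise.delta) ** 2


def sigma_dprime_sq(noise: NoiseSpec) -> float:
    """Effective persistence noise intensity
    sigma''^2 = sigma^2 + int_Y gamma^2(u)/(1-delta)^2 lambda(du)."""
    if noise.delta >= 1.0:
        raise ValidationError(f"sigma_dprime_sq requires delta < 1, got {noise.delta!r}")
    return noise.sigma**2 + noise.int_gamma_sq / (1.0 - noise.delta) ** 2


def check_assumption1(
    noise: NoiseSpec, coeffs: DerivedCoefficients
) -> tuple[bool, float]:
    """Jump-size assumption |K * gamma(u)| <= delta < 1 over the mark support.

    Returns (holds, margin) with margin = delta - sup|K * gamma(u)|; a
    negative margin means the assumption fails.
    """
    sup_kg = abs(coeffs.K) * noise.mark.sup_abs()
    margin = noise.delta - sup_kg
    return (margin >= 0.0 and noise.delta < 1.0), margin


def extinction_condition_a(
    coeffs: DerivedCoefficients, noise: NoiseSpec
) -> tuple[bool, float]:
    """Condition (a): sigma'^2 > c1^2/(2*b2), strictly.

    Returns (holds, margin) with margin = sigma'^2 - c1^2/(2*b2).  Note the
    threshold is negative whenever b2 < 0, in which case any noise level
    satisfies the printed inequality.
    """
    if coeffs.b2 == 0.0:
        raise DegenerateParameterError("extinction_condition_a: b2 == 0")
    sp2 = sigma_prime_sq(noise)
    margin = sp2 - coeffs.c1**2 / (2.0 * coeffs.b2)
    return margin > 0.0, margin


def extinction_condition_b(
    coeffs: DerivedCoefficients, noise: NoiseSpec
) -> tuple[bool, tuple[float, float]]:
    """Condition (b): sigma'^2 <= c1/K  and  (c1/b2)*K - (sigma'^2/(2*b2))*K^2 < 1.

    Returns (holds, (margin1, margin2)) with margin1 = c1/K - sigma'^2
    (>= 0 required) and margin2 = 1 - [(c1/b2)*K - (sigma'^2/(2*b2))*K^2]
    (> 0 required).
    """
    if coeffs.K == 0.0:
        raise DegenerateParameterError("extinction_condition_b: K == 0")
    if coeffs.b2 == 0.0:
        raise DegenerateParameterError("extinction_condition_b: b2 == 0")
    sp2 = sigma_prime_sq(noise)
    m1 = coeffs.c1 / coeffs.K - sp2
    expr = (coeffs.c1 / coeffs.b2) * coeffs.K - (sp2 / (2.0 * coeffs.b2)) * coeffs.K**2
    m2 = 1.0 - expr
    return (m1 >= 0.0) and (m2 > 0.0), (m1, m2)


def lyapunov_growth_bound(
    coeffs: DerivedCoefficients, noise: NoiseSpec, which: str
) -> float:
    """Closed-form bound on limsup ln y(t)/t under condition (a) or (b).

    which="a": c1^2/(2*sigma'^2) + b2 (requires sigma'^2 > 0);
    which="b": b2 * [-1 + (c1/b2)*K - (sigma'^2/(2*b2))*K^2].
    """
    sp2 = sigma_prime_sq(noise)
    if which == "a":
        if sp2 == 0.0:
            raise DegenerateParameterError(
                "lyapunov_growth_bound('a') requires sigma'^2 > 0"
            )
        return coeffs.c1**2 / (2.0 * sp2) + coeffs.b2
    if which == "b":
        if coeffs.b2 == 0.0:
            raise DegenerateParameterError("lyapunov_growth_bound('b'): b2 == 0")
        return coeffs.b2 * (
            -1.0
            + (coeffs.c1 / coeffs.b2) * coeffs.K
            - (sp2 / (2.0 * coeffs.b2)) * coeffs.K**2
        )
    raise ValidationError(f"which must be 'a' or 'b', got {which!r}")


def r0(coeffs: DerivedCoefficients) -> float:
    """Deterministic persistence index, adopted as R0 := (c1/b2)*K."""
    if coeffs.b2 == 0.0:
        raise DegenerateParameterError("r0: b2 == 0")
    return (coeffs.c1 / coeffs.b2) * coeffs.K


def r0_star(coeffs: DerivedCoefficients, noise: NoiseSpec) -> float:
    """Stochastic persistence index R0* = R0 - (sigma''^2/(2*b2))*K^2;
    R0* > 1 is the sufficient condition for the reaction to continue."""
    return r0(coeffs) - (sigma_dprime_sq(noise) / (2.0 * coeffs.b2)) * coeffs.K**2


def persistence_lower_bound(
    coeffs: DerivedCoefficients,
    rates: RateConstants,
    init: InitialConditions,
    noise: NoiseSpec,
    variant: str = "statement",
) -> float:
    """Closed-form lower bound on liminf <y>:

    prefactor * [b2/c1 - (sigma''^2/(2*c1))*K^2] + (x0 - c0)

    The theorem statement prints prefactor (2*k_minus1 + k2)/k2 while the
    final line of its proof carries (2*k_minus1 - k2)/k2; both variants are
    computed (``variant`` in {"statement", "proof"}) and reported, with
    "statement" as the default scalar.
    """
    if coeffs.c1 == 0.0:
        raise DegenerateParameterError("persistence_lower_bound: c1 == 0")
    if rates.k2 == 0.0:
        raise DegenerateParameterError("persistence_lower_bound: k2 == 0")
    if variant == "statement":
        pref = (2.0 * rates.k_minus1 + rates.k2) / rates.k2
    elif variant == "proof":
        pref = (2.0 * rates.k_minus1 - rates.k2) / rates.k2
    else:
        raise ValidationError(f"variant must be 'statement' or 'proof', got {variant!r}")
    core = coeffs.b2 / coeffs.c1 - (
        sigma_dprime_sq(noise) / (2.0 * coeffs.c1)
    ) * coeffs.K**2
    return pref * core + (init.x0 - init.c0)


@dataclass
class ThresholdReport:
    """All threshold quantities, condition booleans, margins and the verdict.

    Booleans are consistent with the signs of their margins; ``regime`` is a
    pure function of the four booleans (see :func:`regime_from_flags`).
    ``warnings`` lists flagged discrepancies with the source publication.
    """

    sigma_prime_sq: float
    sigma_dprime_sq: float
    assumption1_ok: bool
    assumption1_margin: float
    cond_a: bool
    cond_a_margin: float
    cond_b: bool
    cond_b_margin_1: float
    cond_b_margin_2: float
    growth_bound_a: float
    growth_bound_b: float
    r0: float
    r0_star: float
    r0_definition: str
    persistence_bound_statement: float
    persistence_bound_proof: float
    region_bound_paper_literal: float
    region_bound_corrected: float
    regime: str
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict:
        return {
            "sigma_prime_sq": self.sigma_prime_sq,
            "sigma_dprime_sq": self.sigma_dprime_sq,
            "assumption1_ok": self.assumption1_ok,
            "assumption1_margin": self.assumption1_margin,
            "cond_a": self.cond_a,
            "cond_a_margin": self.cond_a_margin,
            "cond_b": self.cond_b,
            "cond_b_margin_1": self.cond_b_margin_1,
            "cond_b_margin_2": self.cond_b_margin_2,
            "growth_bound_a": self.growth_bound_a,
            "growth_bound_b": self.growth_bound_b,
            "r0": self.r0,
            "r0_star": self.r0_star,
            "r0_definition": self.r0_definition,
            "persistence_bound_statement": self.persistence_bound_statement,
            "persistence_bound_proof": self.persistence_bound_proof,
            "region_bound_paper_literal": self.region_bound_paper_literal,
            "region_bound_corrected": self.region_bound_corrected,
            "regime": self.regime,
            "warnings": list(self.warnings),
        }


def regime_from_flags(
    assumption1_ok: bool, cond_a: bool, cond_b: bool, persistent_ok: bool
) -> str:
    """Decision table mapping condition booleans to a regime verdict.

    An extinction condition together with R0* > 1 is a ``conflict`` (the
    sufficient conditions are not mutually exclusive on paper); condition
    (a) takes precedence over (b); neither holding with R0* <= 1 is
    ``indeterminate``.  The jump-size assumption does not change the
    verdict (the conditions are evaluated as printed either way) but is
    carried in the report and flagged in its warnings when violated.
    """
    del assumption1_ok  # carried in the report; not part of the verdict
    if (cond_a or cond_b) and persistent_ok:
        return "conflict"
    if cond_a:
        return "end_a"
    if cond_b:
        return "end_b"
    if persistent_ok:
        return "persistent"
    return "indeterminate"


def classify_regime(
    coeffs: DerivedCoefficients,
    rates: RateConstants,
    init: InitialConditions,
    noise: NoiseSpec,
    r0_override: float | None = None,
) -> ThresholdReport:
    """Evaluate every threshold quantity and classify the noise regime.

    Degenerate parameter combinations raise
    :class:`~edacircuit.model.DegenerateParameterError` naming the
    offending quantity.  ``r0_override`` substitutes a user-supplied R0 for
    the adopted definition (the substitution is flagged in the report).
    """
    warnings: List[str] = [PRINTED_CLAIMS_NOTE]
    sp2 = sigma_prime_sq(noise)
    sdp2 = sigma_dprime_sq(noise)
    a1_ok, a1_margin = check_assumption1(noise, coeffs)
    if not a1_ok:
        warnings.append(
            "jump-size assumption |K*gamma(u)| <= delta < 1 is violated "
            f"(margin {a1_margin:.6g}); the theorems' hypotheses do not apply"
        )
    cond_a, margin_a = extinction_condition_a(coeffs, noise)
    cond_b, (margin_b1, margin_b2) = extinction_condition_b(coeffs, noise)
    gb_a = lyapunov_growth_bound(coeffs, noise, "a") if sp2 > 0 else math.inf
    if sp2 == 0:
        warnings.append("sigma'^2 == 0: condition-(a) growth bound undefined (+inf)")
    gb_b = lyapunov_growth_bound(coeffs, noise, "b")
    if r0_override is None:
        r0_val = r0(coeffs)
        r0_def = "adopted:(c1/b2)*K"
        warnings.append(R0_DEFINITION_NOTE)
    else:
        r0_val = float(r0_override)
        r0_def = "override"
        warnings.append("R0 supplied by the caller, overriding the adopted definition")
    r0s = r0_val - (sdp2 / (2.0 * coeffs.b2)) * coeffs.K**2
    persistent_ok = r0s > 1.0
    if coeffs.c1 != 0.0 and rates.k2 != 0.0:
        pb_stmt = persistence_lower_bound(coeffs, rates, init, noise, "statement")
        pb_proof = persistence_lower_bound(coeffs, rates, init, noise, "proof")
    else:
        pb_stmt = pb_proof = math.nan
        warnings.append(
            "persistence lower bound undefined (c1 == 0 or k2 == 0); reported as NaN"
        )
    regime = regime_from_flags(a1_ok, cond_a, cond_b, persistent_ok)
    if regime == "conflict":
        warnings.append(
            "an extinction condition and R0* > 1 hold simultaneously; the "
            "printed sufficient conditions conflict for these parameters"
        )
    return ThresholdReport(
        sigma_prime_sq=sp2,
        sigma_dprime_sq=sdp2,
        assumption1_ok=a1_ok,
        assumption1_margin=a1_margin,
        cond_a=cond_a,
        cond_a_margin=margin_a,
        cond_b=cond_b,
        cond_b_margin_1=margin_b1,
        cond_b_margin_2=margin_b2,
        growth_bound_a=gb_a,
        growth_bound_b=gb_b,
        r0=r0_val,
        r0_star=r0s,
        r0_definition=r0_def,
        persistence_bound_statement=pb_stmt,
        persistence_bound_proof=pb_proof,
        region_bound_paper_literal=coeffs.K,
        region_bound_corrected=init.x0 - init.c0,
        regime=regime,
        warnings=warnings,
    )
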