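"""Two-step mediation MR: product-of-coefficients with Delta-method SE.

Decomposes the total effect of an exposure on an outcome (Beta1, from a
standard univariable MR) into the part transmitted through a mediator —
the indirect effect Beta2*Beta3, where Beta2 is the exposure->mediator and
Beta3 the mediator->outcome MR estimate — and the direct remainder
Beta1 - Beta2*Beta3.  The first-order Delta method gives
``se_indirect = sqrt(Beta3^2 se2^2 + Beta2^2 se3^2)``; the proportion
mediated is the indirect over the total effect, computed on the beta
(log-odds) scale.  Proportions outside [0,1] (inconsistent mediation) are
reported and flagged, never clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import MRResult, Z_95


@dataclass
class MediationResult:
    """Total / indirect / direct decomposition with Delta-method uncertainty."""

    beta_total: float                 # Beta1
    beta_exp_to_med: float            # Beta2
    beta_med_to_out: float            # Beta3
    beta_indirect: float
    se_indirect: float
    ci_indirect: tuple[float, float]
    p_indirect: float
    beta_direct: float
    proportion_mediated: float
    proportion_flag: str = ""         # "", "outside_unit_interval", "total_effect_zero"
    se_sources: dict = field(default_factory=dict)
    estimators: dict = field(default_factory=dict)
    exposure: str = ""
    mediator: str = ""
    outcome: str = ""

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure, "outcome": self.outcome,
            "method": "two_step_mediation", "mediator": self.mediator,
            "beta": self.beta_indirect, "se": self.se_indirect,
            "ci_low": self.ci_indirect[0], "ci_high": self.ci_indirect[1],
            "odds_ratio": math.exp(self.beta_indirect),
            "or_ci_low": math.exp(self.ci_indirect[0]),
            "or_ci_high": math.exp(self.ci_indirect[1]),
            "pvalue": self.p_indirect,
            "beta_total": self.beta_total,
            "beta_exp_to_med": self.beta_exp_to_med,
            "beta_med_to_out": self.beta_med_to_out,
            "beta_direct": self.beta_direct,
            "proportion_mediated": self.proportion_mediated,
            "proportion_flag": self.proportion_flag,
        }

    def summary(self) -> str:
        lines = [
            f"Two-step mediation MR  ({self.exposure or 'X'} -> {self.mediator or 'M'} -> {self.outcome or 'Y'})",
            f"  total effect (Beta1)    = {self.beta_total:.6g}",
            f"  X->M (Beta2)            = {self.beta_exp_to_med:.6g}",
            f"  M->Y (Beta3)            = {self.beta_med_to_out:.6g}",
            f"  indirect (Beta2*Beta3)  = {self.beta_indirect:.6g}  (se {self.se_indirect:.6g})",
            f"  95% CI indirect         = [{self.ci_indirect[0]:.6g}, {self.ci_indirect[1]:.6g}]",
            f"  direct (Beta1-indirect) = {self.beta_direct:.6g}",
            f"  proportion mediated     = {self.proportion_mediated:.4g}"
            + (f"  [{self.proportion_flag}]" if self.proportion_flag else ""),
        ]
        return "\n".join(lines)


def two_step_mediation(total: MRResult, step1: MRResult, step2: MRResult) -> MediationResult:
    """Combine three MR estimates (all on the beta / log-odds scale).

    Parameters
    ----------
    total : MRResult
        Exposure -> outcome (Beta1, the primary MR).
    step1 : MRResult
        Exposure -> mediator (Beta2).
    step2 : MRResult
        Mediator -> outcome (Beta3).
    """
    from scipy import stats

    for r, lab in ((total, "total"), (step1, "step1"), (step2, "step2")):
        if r.status != "ok":
            raise ValueError(f"two_step_mediation: {lab} result is {r.status}")
    b1, b2, b3 = total.beta, step1.beta, step2.beta
    indirect = b2 * b3
    se_ind = math.sqrt(b3**2 * step1.se**2 + b2**2 * step2.se**2)
    ci = (indirect - Z_95 * se_ind, indirect + Z_95 * se_ind)
    p_ind = float(2 * stats.norm.sf(abs(indirect / se_ind))) if se_ind > 0 else (1.0 if indirect == 0 else 0.0)
    direct = b1 - indirect
    if b1 == 0:
        prop, flag = float("nan"), "total_effect_zero"
    else:
        prop = indirect / b1
        flag = "" if 0.0 <= prop <= 1.0 else "outside_unit_interval"
    return MediationResult(
        beta_total=b1, beta_exp_to_med=b2, beta_med_to_out=b3,
        beta_indirect=indirect, se_indirect=se_ind, ci_indirect=ci,
        p_indirect=p_ind, beta_direct=direct, proportion_mediated=prop,
        proportion_flag=flag,
        se_sources={"total": total.se, "step1": step1.se, "step2": step2.se},
        estimators={"total": total.method, "step1": step1.method, "step2": step2.method},
        exposure=total.exposure or step1.exposure,
        mediator=step1.outcome or step2.exposure,
        outcome=total.outcome or step2.outcome,
    )
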