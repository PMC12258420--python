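"""Interval-inclusion decisions for the multivariate TOST and alpha-TOST.

Equivalence is declared when, for every outcome, the equal-tailed
100(1-2*gamma)% t-interval for the mean difference lies inside the margin
interval (-c, c); equivalently when both one-sided statistics
T_l = (theta_hat + c)/se and T_u = (theta_hat - c)/se clear the t critical
value.  The alpha-TOST first computes the adjusted level from the estimated
covariance and runs the identical decision at that (larger) level, falling
back to the nominal level with a warning when the adjustment does not exist.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy import stats

from .adjustment import AdjustmentResult, alpha_star
from .canonical import CanonicalModel, EquivalenceSpec, MCConfig

__all__ = ["OutcomeDecision", "DecisionReport", "tost_decide", "atost_decide"]


@dataclasses.dataclass(frozen=True)
class OutcomeDecision:
    outcome: str
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    t_lower: float
    t_upper: float
    included: bool


@dataclasses.dataclass(frozen=True)
class DecisionReport:
    method: str  # "tost" | "atost"
    level_used: float
    nu: int
    margin_c: float
    alpha_nominal: float
    outcomes: tuple[OutcomeDecision, ...]
    declared: bool
    adjustment: AdjustmentResult | None = None
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "level_used": self.level_used,
            "nu": self.nu,
            "margin_c": self.margin_c,
            "alpha_nominal": self.alpha_nominal,
            "declared": self.declared,
            "notes": list(self.notes),
            "outcomes": [dataclasses.asdict(o) for o in self.outcomes],
        }
        if self.adjustment is not None:
            d["adjustment"] = {
                "alpha_star": self.adjustment.alpha_star,
                "exists": self.adjustment.exists,
                "outer_iters": self.adjustment.outer_iters,
                "omega_kind": self.adjustment.omega_kind,
            }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DecisionReport":
        d = json.loads(text)
        outcomes = tuple(OutcomeDecision(**o) for o in d["outcomes"])
        return cls(
            method=d["method"],
            level_used=d["level_used"],
            nu=d["nu"],
            margin_c=d["margin_c"],
            alpha_nominal=d["alpha_nominal"],
            outcomes=outcomes,
            declared=d["declared"],
            notes=tuple(d.get("notes", ())),
        )

    def to_table(self) -> str:
        """Human-readable decision table, one row per outcome."""
        rows = [
            f"{'outcome':<12} {'estimate':>9} {'lower':>9} {'upper':>9} {'within':>7}"
        ]
        for o in self.outcomes:
            rows.append(
                f"{o.outcome:<12} {o.estimate:>9.4f} {o.ci_lower:>9.4f} "
                f"{o.ci_upper:>9.4f} {'yes' if o.included else 'no':>7}"
            )
        rows.append(
            f"method={self.method}  level={self.level_used:.4f}  "
            f"margins=(-{self.margin_c:.4f}, {self.margin_c:.4f})  "
            f"equivalence declared: {'YES' if self.declared else 'NO'}"
        )
        return "\n".join(rows)


def _decide_at_level(
    model: CanonicalModel, spec: EquivalenceSpec, gamma: float
) -> tuple[tuple[OutcomeDecision, ...], bool]:
    tq = stats.t.isf(gamma, model.nu)
    names = model.outcome_names or tuple(f"y{j + 1}" for j in range(model.m))
    out = []
    for j in range(model.m):
        est = float(model.theta_hat[j])
        se = float(model.sigma_hat_j[j])
        lo, hi = est - tq * se, est + tq * se
        t_l = (est + spec.c) / se
        t_u = (est - spec.c) / se
        included = bool(t_l >= tq and t_u <= -tq)
        out.append(
            OutcomeDecision(
                outcome=names[j],
                estimate=est,
                se=se,
                ci_lower=lo,
                ci_upper=hi,
                t_lower=t_l,
                t_upper=t_u,
                included=included,
            )
        )
    return tuple(out), all(o.included for o in out)


def tost_decide(
    model: CanonicalModel, spec: EquivalenceSpec, *, level: float | None = None
) -> DecisionReport:
    """Conventional multivariate TOST decision at the nominal level.

    ``level`` overrides the test level (used internally by the alpha-TOST);
    the statistic-based and interval-based criteria agree exactly.
    """
    gamma = spec.alpha if level is None else float(level)
    outcomes, declared = _decide_at_level(model, spec, gamma)
    return DecisionReport(
        method="tost",
        level_used=gamma,
        nu=model.nu,
        margin_c=spec.c,
        alpha_nominal=spec.alpha,
        outcomes=outcomes,
        declared=declared,
    )


def atost_decide(
    model: CanonicalModel,
    spec: EquivalenceSpec,
    mc: MCConfig | None = None,
    **adjust_kwargs,
) -> DecisionReport:
    """Multivariate alpha-TOST: adjust the level from Sigma_hat, then decide.

    The same adjusted level is applied to every outcome's interval.  The
    intervals can only shrink relative to the conventional TOST, so the
    alpha-TOST declares whenever the TOST does.
    """
    adj = alpha_star(
        model.sigma_hat_mat, model.nu, spec, mc=mc, omega_kind="estimated",
        **adjust_kwargs,
    )
    notes: list[str] = []
    if adj.exists:
        gamma = adj.alpha_star
    else:
        gamma = spec.alpha
        notes.append(
            "adjusted level does not exist for this covariance; "
            "falling back to the conventional TOST level"
        )
    outcomes, declared = _decide_at_level(model, spec, gamma)
    return DecisionReport(
        method="atost",
        level_used=gamma,
        nu=model.nu,
        margin_c=spec.c,
        alpha_nominal=spec.alpha,
        outcomes=outcomes,
        declared=declared,
        adjustment=adj,
        notes=tuple(notes),
    )
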