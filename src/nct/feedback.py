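"""ErbB-cargo feedback extension and switch-like ultrasensitivity analysis.

Internalized ErbB heterodimers are modeled as classical Imp-α:Imp-β cargo.
Two antagonistic proportional feedbacks close the loop at steady state:

* cytoplasmic ErbB induces CSE1L (CAS), raising its effective abundance —
  a positive feedback, because CAS lowers classical-cargo import;
* nuclear ErbB represses KPNA1 via miR-205, lowering effective Imp-α —
  a negative feedback on import that further favors the cytoplasmic state.

The feedbacks are algebraic constraints on the effective totals, co-solved
with the transport steady state by damped fixed-point iteration.  Scanning
initial CSE1L abundance yields a C/N (= 1 / N/C) dose response whose
steepness is quantified as an apparent Hill coefficient (max log-log slope)
and a 10→90% transition width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .config import ModelConfig
from .network import CYTOPLASM, NUCLEUS
from .transport import CargoSpec, add_cargo, build_network, steady_state

__all__ = [
    "ErbbCargo",
    "FeedbackParams",
    "SwitchCurve",
    "FeedbackModel",
    "build_feedback_model",
    "cn_curve",
    "ultrasensitivity_index",
    "KD_LADDER",
]

#: illustrative Imp-α:Imp-β affinity ladder for strong/medium/weak ErbB NLSs
KD_LADDER = {"strong": 2.5, "medium": 32.0, "weak": 320.0}


@dataclass(frozen=True)
class ErbbCargo:
    kd_import: float = 2.5  # nM
    total_concentration: float = 1.0  # µM
    kon: float = 1.0  # µM⁻¹s⁻¹; faster than the reporter default, so that
                      # affinity (via k_off) shapes the dose response

    def __post_init__(self):
        if not self.kd_import > 0:
            raise ValueError("kd_import must be > 0")

    def spec(self) -> CargoSpec:
        return CargoSpec("ErbB", "classical", self.kd_import,
                         total_concentration=self.total_concentration,
                         kon=self.kon)


@dataclass(frozen=True)
class FeedbackParams:
    gain_cas: float = 8.0
    gain_impa: float = 0.3
    enabled: bool = True

    def __post_init__(self):
        if self.gain_cas < 0 or self.gain_impa < 0:
            raise ValueError("gains must be >= 0")


@dataclass
class SwitchCurve:
    folds: np.ndarray          # initial CSE1L abundance, fold of base
    cn: np.ndarray             # steady-state C/N per point
    converged: np.ndarray      # per-point convergence flags
    branch: str = "forward"    # continuation direction

    def __post_init__(self):
        self.folds = np.asarray(self.folds, float)
        self.cn = np.asarray(self.cn, float)
        self.converged = np.asarray(self.converged, bool)
        if np.any(np.diff(self.folds) <= 0):
            raise ValueError("fold grid must be strictly increasing")


class FeedbackModel:
    """Transport model with ErbB cargo and effective-abundance feedbacks."""

    def __init__(self, config: ModelConfig, cargo: ErbbCargo, fb: FeedbackParams):
        self.config = config
        self.cargo = cargo
        self.fb = fb
        self.base_cas = config.species["CAS"][0]
        self.base_impa = config.species["ImpA"][0]

    def _solve_at(self, cas_tot: float, impa_tot: float):
        cfg = self.config.with_species({"CAS": cas_tot, "ImpA": impa_tot})
        model = add_cargo(build_network(cfg), self.cargo.spec())
        res = steady_state(model, "ErbB")
        net = model.network
        amt = {
            comp: sum(
                res.x[i] * net.compartments[comp].volume
                for i in model.cargo_states("ErbB", comp)
            )
            for comp in net.compartments
        }
        total = sum(amt.values())
        return res, amt[CYTOPLASM] / total, amt[NUCLEUS] / total

    def solve(self, cse1l_fold: float = 1.0, damping: float = 0.5,
              tol: float = 1e-6, max_iter: int = 200,
              start: tuple[float, float] | None = None):
        """Co-solve the steady state with the feedback constraints.

        Returns (SteadyStateResult, info) where info records the effective
        totals, the ErbB compartment fractions, the constraint residual and
        whether the fixed point converged.
        """
        cas0 = self.base_cas * cse1l_fold
        impa0 = self.base_impa
        if not self.fb.enabled or (self.fb.gain_cas == 0 and self.fb.gain_impa == 0):
            res, f_cyt, f_nuc = self._solve_at(cas0, impa0)
            return res, {
                "cas_eff": cas0, "impa_eff": impa0, "frac_cyt": f_cyt,
                "frac_nuc": f_nuc, "fixed_point_converged": res.converged,
                "constraint_residual": 0.0, "iterations": 1,
            }

        cas_eff, impa_eff = start if start is not None else (cas0, impa0)
        converged = False
        res = None
        for it in range(1, max_iter + 1):
            res, f_cyt, f_nuc = self._solve_at(cas_eff, impa_eff)
            cas_target = cas0 * (1.0 + self.fb.gain_cas * f_cyt)
            impa_target = impa0 * max(0.0, 1.0 - self.fb.gain_impa * f_nuc)
            delta = max(
                abs(cas_target - cas_eff) / max(cas0, 1e-12),
                abs(impa_target - impa_eff) / max(impa0, 1e-12),
            )
            cas_eff = (1 - damping) * cas_eff + damping * cas_target
            impa_eff = (1 - damping) * impa_eff + damping * impa_target
            if delta < tol:
                converged = True
                break
        if impa_eff <= 0:
            raise ValueError("feedback drives effective Imp-α to zero (degenerate)")
        return res, {
            "cas_eff": cas_eff, "impa_eff": impa_eff, "frac_cyt": f_cyt,
            "frac_nuc": f_nuc, "fixed_point_converged": converged and res.converged,
            "constraint_residual": delta, "iterations": it,
        }


def build_feedback_model(config: ModelConfig, cargo: ErbbCargo,
                         fb: FeedbackParams) -> FeedbackModel:
    return FeedbackModel(config, cargo, fb)


def cn_curve(model: FeedbackModel, cse1l_folds, direction: str = "forward") -> SwitchCurve:
    """Steady-state C/N of ErbB across initial CSE1L abundances.

    Continuation: each point starts the fixed-point iteration from the
    previous point's effective totals ("forward" = low→high CSE1L,
    "backward" = high→low), so a bistable region resolves to the branch
    reachable from that end of the grid.
    """
    folds = np.asarray(cse1l_folds, float)
    if folds.ndim != 1 or len(folds) < 10:
        raise ValueError("need a grid of >= 10 points")
    if np.any(folds <= 0) or np.any(np.diff(folds) <= 0):
        raise ValueError("fold grid must be positive and strictly increasing")
    order = range(len(folds)) if direction == "forward" else range(len(folds) - 1, -1, -1)
    cn = np.empty(len(folds))
    ok = np.zeros(len(folds), bool)
    start = None
    for i in order:
        res, info = model.solve(folds[i], start=start)
        start = (info["cas_eff"], info["impa_eff"])
        nc = res.nc_ratio
        cn[i] = np.inf if nc == 0 else 1.0 / nc
        ok[i] = info["fixed_point_converged"]
    return SwitchCurve(folds, cn, ok, branch=direction)


def detect_bistability(model: FeedbackModel, cse1l_folds, rel_tol: float = 1e-3):
    """Compare forward and backward continuation; a gap flags bistability."""
    fwd = cn_curve(model, cse1l_folds, "forward")
    bwd = cn_curve(model, cse1l_folds, "backward")
    gap = np.abs(fwd.cn - bwd.cn) / np.maximum(np.abs(fwd.cn), 1e-12)
    return fwd, bwd, bool(np.any(gap > rel_tol))


def ultrasensitivity_index(curve: SwitchCurve) -> dict:
    """Quantify switch-likeness of a monotone dose response.

    Returns the maximum local log-log slope (apparent Hill coefficient,
    central differences) and the fold-range of the input spanning 10%→90%
    of the response span (interpolated in log-input).  A non-monotone curve
    is first fit by isotonic regression and flagged.
    """
    x = np.log(curve.folds)
    y = np.asarray(curve.cn, float)
    if len(x) < 10:
        raise ValueError("need >= 10 points")
    monotone = bool(np.all(np.diff(y) >= 0) or np.all(np.diff(y) <= 0))
    if not monotone:
        increasing = y[-1] >= y[0]
        y = IsotonicRegression(increasing=increasing).fit_transform(x, y)
    ylog = np.log(np.maximum(y, 1e-300))
    slopes = (ylog[2:] - ylog[:-2]) / (x[2:] - x[:-2])
    edge = [(ylog[1] - ylog[0]) / (x[1] - x[0]), (ylog[-1] - ylog[-2]) / (x[-1] - x[-2])]
    max_slope = float(np.max(np.abs(np.concatenate([[edge[0]], slopes, [edge[1]]]))))

    lo = y.min() + 0.1 * (y.max() - y.min())
    hi = y.min() + 0.9 * (y.max() - y.min())
    yy = y if y[-1] >= y[0] else y[::-1]
    xx = x if y[-1] >= y[0] else -x[::-1]
    x10 = np.interp(lo, yy, xx)
    x90 = np.interp(hi, yy, xx)
    width = float(np.exp(abs(x90 - x10)))
    return {
        "max_loglog_slope": max_slope,
        "transition_width_fold": width,
        "monotone_input": monotone,
    }
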