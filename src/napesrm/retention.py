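"""Equivalent-carbon-number retention modeling for reversed-phase NAPE runs.

Reversed-phase retention of glycerophospholipids grows with the total acyl
carbon count and shrinks with each double bond.  The classic ECN predictor
collapses both into a single number (ECN = C - k*DB); here the two effects
get separate linear coefficients, which strictly generalizes ECN (ECN
corresponds to db_coeff / carbon_coeff = -k).  The fitted model schedules
acquisition windows and flags species whose observed retention is
inconsistent with their homologous series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lipid_model import NapeSpecies

__all__ = ["RetentionModel", "fit_retention", "predict_rt", "flag_outliers"]

DEFAULT_RUN_LENGTH_MIN = 18.0


@dataclass
class RetentionModel:
    """Linear RT model: rt = intercept + carbon_coeff*(C+n) + db_coeff*(D+dn)."""

    intercept: float
    carbon_coeff: float  # minutes per acyl carbon
    db_coeff: float  # minutes per double bond
    residual_sd: float = 0.0
    n_fit: int = 0
    run_length_min: float = DEFAULT_RUN_LENGTH_MIN

    def predict_rt(self, species: NapeSpecies) -> float:
        return predict_rt(self, species)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "carbon_coeff": self.carbon_coeff,
            "db_coeff": self.db_coeff,
            "residual_sd": self.residual_sd,
            "n_fit": self.n_fit,
            "run_length_min": self.run_length_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RetentionModel":
        return cls(**d)


def _design(observations: Sequence[tuple[NapeSpecies, float]]):
    carbons = np.array([sp.total_carbons for sp, _ in observations], dtype=float)
    dbs = np.array([sp.total_double_bonds for sp, _ in observations], dtype=float)
    rts = np.array([rt for _, rt in observations], dtype=float)
    X = np.column_stack([np.ones_like(carbons), carbons, dbs])
    return X, rts, carbons, dbs


def fit_retention(
    observations: Sequence[tuple[NapeSpecies, float]],
    run_length_min: float = DEFAULT_RUN_LENGTH_MIN,
) -> RetentionModel:
    """Ordinary least squares of RT (minutes) on total carbons and double bonds.

    Requires at least three observations with variation in both predictors.
    Warns (without failing) if the fitted signs contradict the expected
    reversed-phase behavior (carbons retained more, double bonds less).
    """
    if len(observations) < 3:
        raise ValueError("need at least 3 retention observations")
    X, rts, carbons, dbs = _design(observations)
    if np.unique(carbons).size < 2:
        raise ValueError("no variation in total carbon number; cannot fit carbon_coeff")
    if np.unique(dbs).size < 2:
        raise ValueError("no variation in total double bonds; cannot fit db_coeff")
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError(
            "rank-deficient design: carbons and double bonds are collinear "
            "across the observations"
        )
    beta, _, _, _ = np.linalg.lstsq(X, rts, rcond=None)
    resid = rts - X @ beta
    dof = len(observations) - 3
    residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    model = RetentionModel(
        intercept=float(beta[0]),
        carbon_coeff=float(beta[1]),
        db_coeff=float(beta[2]),
        residual_sd=residual_sd,
        n_fit=len(observations),
        run_length_min=run_length_min,
    )
    if model.carbon_coeff <= 0:
        warnings.warn(
            "fitted carbon coefficient is not positive; retention normally "
            "increases with acyl carbons on reversed phase",
            stacklevel=2,
        )
    if model.db_coeff >= 0:
        warnings.warn(
            "fitted double-bond coefficient is not negative; double bonds "
            "normally decrease reversed-phase retention",
            stacklevel=2,
        )
    return model


def predict_rt(model: RetentionModel, species: NapeSpecies) -> float:
    """Predicted retention time in minutes, clipped to [0, run length]."""
    rt = (
        model.intercept
        + model.carbon_coeff * species.total_carbons
        + model.db_coeff * species.total_double_bonds
    )
    if rt < 0 or rt > model.run_length_min:
        warnings.warn(
            f"predicted RT {rt:.2f} min for {species.name} falls outside the "
            f"run; clipping to [0, {model.run_length_min}]",
            stacklevel=2,
        )
        rt = min(max(rt, 0.0), model.run_length_min)
    return float(rt)


def flag_outliers(
    model: RetentionModel,
    observations: Sequence[tuple[NapeSpecies, float]],
    k: float = 3.0,
) -> list[NapeSpecies]:
    """Species whose |observed - predicted| exceeds k times the residual SD."""
    if k <= 0:
        raise ValueError("k must be positive")
    if np.isinf(k):
        return []
    # Floor guards the noiseless case, where residual_sd is 0 but OLS
    # residuals are still ~1e-14 from floating point.
    threshold = max(k * model.residual_sd, 1e-9)
    flagged = []
    for sp, rt in observations:
        # Raw linear prediction: run-length clipping would fake residuals
        # for species eluting near the end of the gradient.
        pred = (
            model.intercept
            + model.carbon_coeff * sp.total_carbons
            + model.db_coeff * sp.total_double_bonds
        )
        if abs(rt - pred) > threshold:
            flagged.append(sp)
    return flagged
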