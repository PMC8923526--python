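"""Model/Results interface over the sparse linear machinery.

``AnthesisLassoModel`` is built from data (a standardized metabolite matrix
plus per-sample anthesis rates, optionally environmental features) and fits
the L1-penalized linear model.  ``fit`` returns a ``LassoResults`` carrying
coefficients and diagnostics; ``sweep`` returns ``SweepResults`` over the
alpha grid, from which the predictor panel is selected at the elbow.

Model variants mirror the study design: 'metabolome' (M), 'environment'
(E) and 'combined' (C), differing only in which feature columns enter X.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lasso
from .lasso import DesignMatrix, LassoSolution, SweepRecord
from .preprocess import MetaboliteMatrix, standardize


VARIANT_KINDS = {
    "metabolome": ("metabolite",),
    "environment": ("environment",),
    "combined": ("metabolite", "environment"),
}


class AnthesisLassoModel:
    """LASSO linear model of the anthesis rate.

    Parameters
    ----------
    design
        standardized feature matrix with the per-sample response.
    """

    def __init__(self, design: DesignMatrix):
        self.design = design

    @classmethod
    def from_matrix(
        cls,
        matrix: MetaboliteMatrix,
        y: pd.Series | np.ndarray,
        environment: pd.DataFrame | None = None,
        variant: str = "metabolome",
    ) -> "AnthesisLassoModel":
        """Build the model from a metabolite matrix (standardized here if it
        is not already) and an optional environmental-factor table aligned
        on samples; ``variant`` selects the feature kinds retained."""
        if variant not in VARIANT_KINDS:
            raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANT_KINDS)}")
        if matrix.state != "standardized":
            matrix = standardize(matrix)
        X = matrix.values.to_numpy()
        ids = list(matrix.values.columns)
        kinds = ["metabolite"] * len(ids)
        if environment is not None:
            env = environment.loc[matrix.values.index]
            env_z = (env - env.mean(axis=0)) / env.std(axis=0, ddof=0)
            X = np.hstack([X, env_z.to_numpy()])
            ids += list(env.columns)
            kinds += ["environment"] * env.shape[1]
        y_arr = np.asarray(y, dtype=float)
        design = DesignMatrix(X, y_arr, ids, kinds).select_kind(VARIANT_KINDS[variant])
        return cls(design)

    def fit(self, alpha: float, **kwargs) -> "LassoResults":
        sol = lasso.fit_lasso(self.design, alpha, **kwargs)
        return LassoResults(self, sol)

    def sweep(
        self,
        alpha_grid: np.ndarray | None = None,
        k: int = 10,
        seed: int = 0,
        **kwargs,
    ) -> "SweepResults":
        records = lasso.alpha_sweep(self.design, alpha_grid, k=k, seed=seed, **kwargs)
        return SweepResults(self, records, k=k, seed=seed)


@dataclass
class LassoResults:
    """Fitted coefficients, goodness of fit and diagnostics at one alpha."""

    model: AnthesisLassoModel
    solution: LassoSolution

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.solution.w, index=self.model.design.feature_ids, name="w")

    @property
    def intercept(self) -> float:
        return self.solution.w0

    @property
    def alpha(self) -> float:
        return self.solution.alpha

    @property
    def support_ids(self) -> list[str]:
        return self.solution.support_ids

    def predict(self, X_new: np.ndarray | None = None) -> np.ndarray:
        X = self.model.design.X if X_new is None else np.asarray(X_new, dtype=float)
        return lasso.predict(self.solution, X)

    @property
    def rsquared(self) -> float:
        return lasso.r2_score(self.model.design.y, self.predict())

    @property
    def mse(self) -> float:
        return lasso.mse(self.model.design.y, self.predict())

    @property
    def kkt_residual(self) -> float:
        return lasso.kkt_residual(self.model.design, self.solution)

    def summary(self) -> str:
        s = self.solution
        lines = [
            "LASSO anthesis-rate model",
            "=" * 48,
            f"n samples            {self.model.design.n}",
            f"m features           {self.model.design.m}",
            f"alpha                {s.alpha:.6g}",
            f"selected features    {len(s.support)}",
            f"intercept (fl/week)  {s.w0:.4f}",
            f"train R^2            {self.rsquared:.4f}",
            f"train MSE            {self.mse:.4f}",
            f"converged            {s.converged} ({s.n_sweeps} sweeps)",
            f"KKT residual         {self.kkt_residual:.2e}",
            "-" * 48,
            "nonzero coefficients (rate units per z-unit):",
        ]
        p = self.params
        nz = p[p != 0].sort_values(key=np.abs, ascending=False)
        for name, val in nz.items():
            lines.append(f"  {name:<24s} {val:+.4f}")
        return "\n".join(lines)


class SweepResults:
    """Regularization path with cross-validation metrics and panel selection."""

    def __init__(self, model: AnthesisLassoModel, records: list[SweepRecord],
                 k: int, seed: int):
        self.model = model
        self.records = records
        self.k = k
        self.seed = seed

    @property
    def frame(self) -> pd.DataFrame:
        return lasso.sweep_frame(self.records)

    def select_elbow(self, tol: float = 0.02) -> SweepRecord:
        return lasso.select_elbow(self.records, tol=tol)

    def select_min_cv_mse(self) -> SweepRecord:
        return lasso.select_min_cv_mse(self.records)

    def results_at(self, record: SweepRecord) -> LassoResults:
        if record.solution is None:
            return self.model.fit(record.alpha)
        return LassoResults(self.model, record.solution)

    def summary(self, tol: float = 0.02) -> str:
        chosen = self.select_elbow(tol)
        f = self.frame
        lines = [
            "LASSO regularization path",
            "=" * 48,
            f"alpha grid           [{f.alpha.min():.3g}, {f.alpha.max():.3g}] "
            f"({len(f)} points, {self.k}-fold CV, seed {self.seed})",
            f"best CV R^2          {f.cv_r2.max():.4f}",
            f"elbow alpha          {chosen.alpha:.6g}",
            f"elbow support size   {chosen.support_size}",
            f"elbow train R^2      {chosen.train_r2:.4f}",
            f"elbow CV R^2         {chosen.cv_r2:.4f}",
            f"elbow CV MSE         {chosen.cv_mse:.4f}",
        ]
        return "\n".join(lines)

    def plot_path(self, ax=None, tol: float = 0.02):
        """Support size vs train/CV R^2 along the path, elbow marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.frame.sort_values("support_size")
        ax.plot(f.support_size, f.train_r2, "o-", label="train $R^2$")
        ax.plot(f.support_size, f.cv_r2, "s-", label="CV $R^2$")
        chosen = self.select_elbow(tol)
        ax.axvline(chosen.support_size, ls=":", color="k",
                   label=f"elbow ({chosen.support_size} metabolites)")
        ax.set_xlabel("number of predictor metabolites")
        ax.set_ylabel("$R^2$")
        ax.legend()
        return ax
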