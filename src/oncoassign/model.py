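"""Model/Results API over the functional core.

Two fitted-model families, in the familiar build-fit-results idiom:

>>> res = ODTModel(Y, X, min_group_size=10).fit()
>>> print(res.summary())
>>> res.predict(X_new)

:class:`ODTModel` fits the optimal decision tree;
:class:`VoteSplitLassoModel` builds the vote matrix and fits the
penalized soft-label multinomial regression.  Both Results objects carry
the training assignment, the per-patient excess over the Oracle, and a
``method_spec()`` adapter for the cross-validation harness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import Assignment, BiomarkerMatrix, SensitivityMatrix, check_aligned
from .evaluation import MethodSpec, delta_ic50
from .multinomial import (
    MultinomialModel,
    build_vote_matrix,
    count_selected_variables,
    fit_multinomial,
    predict_multinomial,
)
from .normalization import TransformSpec
from .odt import ODTConfig, fit_tree, predict_tree
from .tree import DecisionTree, write_tree

__all__ = [
    "ODTModel",
    "ODTResults",
    "VoteSplitLassoModel",
    "VoteSplitLassoResults",
    "constant_best_drug_spec",
]


class ODTModel:
    """Optimal decision tree for per-patient drug assignment."""

    def __init__(
        self,
        sensitivity: SensitivityMatrix,
        biomarkers: BiomarkerMatrix,
        *,
        min_group_size: int = 10,
        transform: str = "identity",
        threshold_policy: str = "midpoints",
        max_depth: int | None = None,
        missing_policy: str = "error",
    ) -> None:
        check_aligned(sensitivity, biomarkers)
        self.sensitivity = sensitivity
        self.biomarkers = biomarkers
        self.config = ODTConfig(
            min_group_size=min_group_size,
            transform=TransformSpec(kind=transform),
            threshold_policy=threshold_policy,
            max_depth=max_depth,
            missing_policy=missing_policy,
        )

    @classmethod
    def from_dataframes(
        cls,
        sensitivity: pd.DataFrame,
        biomarkers: pd.DataFrame,
        *,
        scale: str = "log_ic50",
        **kwargs,
    ) -> "ODTModel":
        return cls(
            SensitivityMatrix.from_frame(sensitivity, scale=scale),
            BiomarkerMatrix.from_frame(biomarkers),
            **kwargs,
        )

    def fit(self) -> "ODTResults":
        tree, assignment = fit_tree(
            self.sensitivity, self.biomarkers, self.config, return_assignment=True
        )
        return ODTResults(self, tree, assignment)


class ODTResults:
    """Fitted tree plus training-cohort diagnostics."""

    def __init__(self, model: ODTModel, tree: DecisionTree, assignment: Assignment):
        self.model = model
        self.tree = tree
        self.training_assignment = assignment
        self.training_delta = delta_ic50(assignment, model.sensitivity)

    def predict(self, biomarkers: BiomarkerMatrix) -> Assignment:
        return predict_tree(self.tree, biomarkers)

    @property
    def n_variables(self) -> int:
        return len(self.tree.markers_used())

    def to_json(self) -> str:
        return write_tree(self.tree, "json")

    def to_dot(self) -> str:
        return write_tree(self.tree, "dot")

    def summary(self) -> str:
        y = self.model.sensitivity
        lines = [
            "Optimal Decision Tree Results",
            "=" * 46,
            f"No. patients:        {y.n_patients}",
            f"No. drugs:           {y.n_drugs}",
            f"Response scale:      {y.scale}",
            f"Transform:           {self.tree.response_transform}",
            f"Min group size:      {self.tree.min_group_size}",
            f"Tree depth:          {self.tree.depth()}",
            f"Splits / leaves:     {self.tree.n_splits()} / {len(self.tree.leaves())}",
            f"Markers used:        {', '.join(self.tree.markers_used()) or '(none)'}",
            f"Training median excess over Oracle: {np.nanmedian(self.training_delta):.4f}",
            f"Training mean excess over Oracle:   {np.nanmean(self.training_delta):.4f}",
            "-" * 46,
            write_tree(self.tree, "text"),
        ]
        return "\n".join(lines)

    def method_spec(self) -> MethodSpec:
        """Adapter: refit this configuration inside the CV harness."""
        config = self.model.config

        def fit(y_train: SensitivityMatrix, x_train: BiomarkerMatrix):
            return fit_tree(y_train, x_train, config)

        return MethodSpec(
            name=f"ODT ({self.tree.response_transform})",
            fit=fit,
            predict=lambda tree, x_test: predict_tree(tree, x_test),
            variable_count=lambda tree: len(tree.markers_used()),
        )


class VoteSplitLassoModel:
    """Soft-label multinomial lasso over vote-split sensitivity labels."""

    def __init__(
        self,
        sensitivity: SensitivityMatrix,
        biomarkers: BiomarkerMatrix,
        *,
        K: float = 1.0,
        penalty: str = "grouped_lasso",
        min_mode: str = "per_patient",
        positivity: str = "strict",
    ) -> None:
        check_aligned(sensitivity, biomarkers)
        self.sensitivity = sensitivity
        self.biomarkers = biomarkers
        self.K = K
        self.penalty = penalty
        self.min_mode = min_mode
        self.positivity = positivity
        self.votes = build_vote_matrix(
            sensitivity, K, min_mode=min_mode, positivity=positivity
        )

    @classmethod
    def from_dataframes(
        cls,
        sensitivity: pd.DataFrame,
        biomarkers: pd.DataFrame,
        *,
        scale: str = "log_ic50",
        **kwargs,
    ) -> "VoteSplitLassoModel":
        return cls(
            SensitivityMatrix.from_frame(sensitivity, scale=scale),
            BiomarkerMatrix.from_frame(biomarkers),
            **kwargs,
        )

    def fit(
        self,
        lam: float | str = "cv",
        folds: int = 5,
        seed: int | None = None,
        **solver_kwargs,
    ) -> "VoteSplitLassoResults":
        fitted = fit_multinomial(
            self.biomarkers,
            self.votes,
            penalty=self.penalty,
            lam=lam,
            folds=folds,
            seed=seed,
            **solver_kwargs,
        )
        return VoteSplitLassoResults(self, fitted)


class VoteSplitLassoResults:
    """Fitted coefficients, selection diagnostics and CV path."""

    def __init__(self, model: VoteSplitLassoModel, fitted: MultinomialModel):
        self.model = model
        self.fitted = fitted
        self.training_assignment = predict_multinomial(fitted, model.biomarkers)
        self.training_delta = delta_ic50(self.training_assignment, model.sensitivity)

    @property
    def params(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fitted.beta, index=self.fitted.marker_names, columns=self.fitted.drug_names
        )

    @property
    def intercepts(self) -> pd.Series:
        return pd.Series(self.fitted.intercepts, index=self.fitted.drug_names)

    @property
    def n_variables(self) -> int:
        return count_selected_variables(self.fitted)

    @property
    def selected_markers(self) -> list[str]:
        keep = np.any(np.abs(self.fitted.beta) > 1e-8, axis=1)
        return [m for m, k in zip(self.fitted.marker_names, keep) if k]

    def predict(self, biomarkers: BiomarkerMatrix) -> Assignment:
        return predict_multinomial(self.fitted, biomarkers)

    def summary(self) -> str:
        f = self.fitted
        lines = [
            "Vote-Split Multinomial Lasso Results",
            "=" * 46,
            f"No. patients:        {self.model.sensitivity.n_patients}",
            f"No. drugs:           {len(f.drug_names)}",
            f"No. markers:         {len(f.marker_names)}",
            f"Vote temperature K:  {self.model.K:g}",
            f"Penalty:             {f.penalty}",
            f"Lambda:              {f.lam:.6g}" + ("  (CV-selected)" if f.cv_path is not None else ""),
            f"Selected variables:  {self.n_variables}",
            f"Converged:           {f.converged} ({f.n_iter} iterations)",
            f"Penalized objective: {f.objective:.6f}",
            f"Training median excess over Oracle: {np.nanmedian(self.training_delta):.4f}",
        ]
        if self.selected_markers:
            lines.append(f"Markers: {', '.join(self.selected_markers[:15])}"
                         + (" ..." if len(self.selected_markers) > 15 else ""))
        return "\n".join(lines)

    def plot_cv_path(self, ax=None):
        """Mean held-out deviance along the regularization path."""
        import matplotlib.pyplot as plt

        if self.fitted.cv_path is None:
            raise ValueError("model was fitted at a fixed lambda; no CV path")
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        lams, devs = zip(*self.fitted.cv_path)
        ax.semilogx(lams, devs, marker=".", ms=3)
        ax.axvline(self.fitted.lam, ls="--", c="gray")
        ax.set_xlabel(r"$\lambda$")
        ax.set_ylabel("mean CV deviance")
        return ax

    def method_spec(self, lam: float | str | None = None, folds: int = 5,
                    seed: int | None = None) -> MethodSpec:
        model = self.model
        lam = self.fitted.lam if lam is None else lam
        seed = self.fitted.cv_seed if seed is None else seed

        def fit(y_train: SensitivityMatrix, x_train: BiomarkerMatrix):
            votes = build_vote_matrix(
                y_train, model.K, min_mode=model.min_mode, positivity=model.positivity
            )
            return fit_multinomial(
                x_train, votes, penalty=model.penalty, lam=lam, folds=folds, seed=seed
            )

        return MethodSpec(
            name=f"Multinomial ({model.penalty})",
            fit=fit,
            predict=lambda state, x_test: predict_multinomial(state, x_test),
            variable_count=count_selected_variables,
        )


def constant_best_drug_spec(name: str = "best single drug") -> MethodSpec:
    """Baseline: always recommend the drug with the best training mean."""

    def fit(y_train: SensitivityMatrix, _x: BiomarkerMatrix) -> str:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(y_train.values, axis=0)
        if y_train.higher_is_better:
            return y_train.drug_names[int(np.nanargmax(means))]
        return y_train.drug_names[int(np.nanargmin(means))]

    def predict(drug: str, x_test: BiomarkerMatrix) -> Assignment:
        return Assignment(list(x_test.patient_ids), [drug] * x_test.n_patients)

    return MethodSpec(name=name, fit=fit, predict=predict, variable_count=lambda _s: 0)
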