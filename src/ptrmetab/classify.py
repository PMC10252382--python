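"""Repeated-split Random Forest classification of treated vs control samples.

Each iteration draws a stratified 70/30 train/test split of the metabolite
profiles, fits a Random Forest, and records test errors per class and
overall, plus which samples were misclassified.  Splits are keyed on sorted
sample ids with per-iteration derived seeds, so reports are reproducible and
independent of input row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .metabolites import MetaboliteTable, preprocess

__all__ = ["ClassificationReport", "RepeatedRandomForest", "repeated_rf"]

_MAX_SEED = 2**31 - 1


@dataclass
class ClassificationReport:
    """Aggregated results of the repeated train/test iterations."""

    n_iterations: int
    train_fraction: float
    per_class_error: dict[str, float]
    overall_error: float
    per_iteration: pd.DataFrame  # iteration x (overall + one column per class)
    misclassification_counts: pd.Series  # per sample, over all iterations
    test_counts: pd.Series  # times each sample appeared in a test set

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"overall_error\t{self.overall_error}\n")
            for cls, err in self.per_class_error.items():
                fh.write(f"error_{cls}\t{err}\n")
            fh.write(f"n_iterations\t{self.n_iterations}\n")
            fh.write(f"train_fraction\t{self.train_fraction}\n")


class RepeatedRandomForest(BaseEstimator):
    """Random Forest treatment classifier with repeated stratified splits.

    Parameters
    ----------
    n_iterations : number of independent train/test splits (default 200).
    train_fraction : fraction of samples used for training (default 0.70).
    n_estimators : trees per forest (default 500).
    stratify_by_region : include colon region in the stratification labels
        when metadata is available, so every region appears in both halves.
    random_state : master seed; per-iteration seeds are derived from it.

    Attributes
    ----------
    report_ : ClassificationReport over all iterations.
    classes_ : sorted class labels.
    final_estimator_ : forest fitted on all samples (used by ``predict``).
    """

    def __init__(
        self,
        n_iterations: int = 200,
        train_fraction: float = 0.70,
        n_estimators: int = 500,
        stratify_by_region: bool = True,
        random_state: int | None = None,
    ):
        self.n_iterations = n_iterations
        self.train_fraction = train_fraction
        self.n_estimators = n_estimators
        self.stratify_by_region = stratify_by_region
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y: pd.Series, metadata: pd.DataFrame | None = None):
        X = pd.DataFrame(X)
        y = pd.Series(y).reindex(X.index)
        classes = sorted(y.astype(str).unique())
        if len(classes) != 2:
            raise ValueError("exactly two classes required")
        counts = y.value_counts()
        if counts.min() < 3:
            raise ValueError("each class needs >= 3 samples")
        # key everything on sorted sample ids so row order cannot matter
        order = sorted(X.index)
        X = X.loc[order]
        y = y.loc[order].astype(str)
        strat = y.copy()
        if self.stratify_by_region and metadata is not None and "region" in metadata:
            combo = y + "|" + metadata.loc[order, "region"].astype(str)
            if combo.value_counts().min() >= 2:
                strat = combo
        self.classes_ = classes

        ss = np.random.SeedSequence(self.random_state)
        iter_seeds = [
            int(child.generate_state(1)[0] % _MAX_SEED) for child in ss.spawn(self.n_iterations)
        ]
        mis = pd.Series(0, index=X.index, dtype=int)
        tested = pd.Series(0, index=X.index, dtype=int)
        rows = []
        for it, seed in enumerate(iter_seeds):
            for attempt in range(20):
                tr_idx, te_idx = train_test_split(
                    np.arange(len(X)),
                    train_size=self.train_fraction,
                    random_state=(seed + attempt) % _MAX_SEED,
                    stratify=strat.values,
                )
                if y.iloc[tr_idx].nunique() == 2 and y.iloc[te_idx].nunique() >= 1:
                    break
            else:  # pragma: no cover - stratification prevents this
                raise RuntimeError("could not draw a split with both classes in train")
            clf = RandomForestClassifier(
                n_estimators=self.n_estimators, random_state=seed, n_jobs=1
            )
            clf.fit(X.iloc[tr_idx].values, y.iloc[tr_idx].values)
            pred = clf.predict(X.iloc[te_idx].values)
            truth = y.iloc[te_idx].values
            wrong = pred != truth
            row = {"iteration": it, "overall": float(wrong.mean())}
            for cls in classes:
                m = truth == cls
                row[f"error_{cls}"] = float(wrong[m].mean()) if m.any() else np.nan
            rows.append(row)
            te_ids = X.index[te_idx]
            tested.loc[te_ids] += 1
            mis.loc[te_ids[wrong]] += 1

        per_iter = pd.DataFrame(rows).set_index("iteration")
        self.report_ = ClassificationReport(
            n_iterations=self.n_iterations,
            train_fraction=self.train_fraction,
            per_class_error={
                cls: float(per_iter[f"error_{cls}"].mean()) for cls in classes
            },
            overall_error=float(per_iter["overall"].mean()),
            per_iteration=per_iter,
            misclassification_counts=mis,
            test_counts=tested,
        )
        final_seed = int(ss.spawn(1)[0].generate_state(1)[0] % _MAX_SEED)
        self.final_estimator_ = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=final_seed, n_jobs=1
        ).fit(X.values, y.values)
        self._feature_names = list(X.columns)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.final_estimator_.predict(pd.DataFrame(X)[self._feature_names].values)


def repeated_rf(
    table: MetaboliteTable,
    n_iterations: int = 200,
    train_fraction: float = 0.70,
    n_estimators: int = 500,
    seed: int | None = None,
) -> ClassificationReport:
    """Classify treatment from metabolite profiles by repeated RF splits.

    Preprocesses the table (imputation, log2), uses ``treatment`` as the
    label and stratifies splits by treatment and region.  The most
    frequently misclassified samples can be read off
    ``report.misclassification_counts`` together with the table's metadata.
    """
    table = preprocess(table)
    model = RepeatedRandomForest(
        n_iterations=n_iterations,
        train_fraction=train_fraction,
        n_estimators=n_estimators,
        random_state=seed,
    )
    model.fit(table.intensities, table.metadata["treatment"], table.metadata)
    return model.report_
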