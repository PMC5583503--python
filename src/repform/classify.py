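"""Per-exercise technique classification with balanced random forests.

One binary (or multi-class) forest is trained per exercise per client on
that client's own labeled repetitions.  The training set is first
balanced by random undersampling so the classifier is not biased toward
the majority class; the forest then uses 400 bootstrap-sampled trees
with random feature subsetting (sqrt of 306 = 17 candidate features per
split), Gini splitting and unlimited depth — the canonical random-forest
recipe.

The module follows the model/results idiom: :class:`TechniqueForest`
holds the (balanced) design matrix and labels, its :meth:`~TechniqueForest.fit`
returns a :class:`TechniqueForestResults` carrying the trained ensemble,
out-of-bag diagnostics, per-repetition predictions with vote fractions,
and a ``summary()`` table.  The auto-label workflow — propose labels for
unlabeled repetitions, let the professional accept or reject each —
hangs off the results object.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_NAMES, FeatureVector, build_feature_matrix, compute_feature_vector

__all__ = [
    "balance_training_set",
    "TechniqueForest",
    "TechniqueForestResults",
    "AutoLabelProposal",
    "accept_proposal",
    "reject_proposal",
    "UnbalancedTrainingError",
]

DEFAULT_N_TREES = 400
DEFAULT_LABEL = "Acceptable"


class UnbalancedTrainingError(ValueError):
    """Raised when training is attempted on class-unbalanced data."""


def balance_training_set(labels, seed: int = 0) -> list[int]:
    """Indices retained after random undersampling to the minority count.

    Every class keeps exactly the minority-class number of observations;
    the removed observations are drawn uniformly at random (seeded) from
    each overrepresented class.  The returned indices preserve the input
    order.  ``labels`` may be a sequence or a mapping key -> label (in
    which case retained keys are returned instead of indices).
    """
    if hasattr(labels, "items"):
        keys = list(labels.keys())
        retained = balance_training_set([labels[k] for k in keys], seed=seed)
        return [keys[i] for i in retained]
    labels = list(labels)
    counts = Counter(labels)
    if len(counts) < 2:
        raise ValueError(
            "balancing requires at least 2 classes; got only "
            f"{sorted(counts)} — a single-class classifier is undefined"
        )
    target = min(counts.values())
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    for label in counts:  # Counter preserves first-appearance order
        idx = [i for i, l in enumerate(labels) if l == label]
        if len(idx) > target:
            idx = list(rng.choice(idx, size=target, replace=False))
        keep.update(idx)
    return sorted(keep)


@dataclass(frozen=True)
class AutoLabelProposal:
    """A classifier-proposed label for one unlabeled repetition."""

    rep_key: tuple[str, str, int]
    proposed_label: str
    vote_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.vote_fraction <= 1.0:
            raise ValueError("vote_fraction must lie in [0, 1]")


class TechniqueForest:
    """Random-forest technique model for one exercise.

    Parameters
    ----------
    endog : sequence of str
        Per-repetition technique labels.
    exog : (n, 306) array
        Feature matrix in the fixed 306-name order (or ``feature_names``
        order if given).
    exercise : str
        Exercise the model is scoped to.
    n_trees : int
        Ensemble size; 400 by default.
    allow_unbalanced : bool
        Balancing is a hard precondition by default; set True only for
        diagnostic fits.
    """

    def __init__(
        self,
        endog,
        exog,
        exercise: str = "",
        feature_names=FEATURE_NAMES,
        training_keys=None,
        n_trees: int = DEFAULT_N_TREES,
        allow_unbalanced: bool = False,
    ):
        self.endog = list(endog)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != len(self.endog):
            raise ValueError("exog must be (n_obs, n_features) aligned with endog")
        self.exercise = exercise
        self.feature_names = tuple(feature_names)
        if self.exog.shape[1] != len(self.feature_names):
            raise ValueError(
                f"exog has {self.exog.shape[1]} columns, expected {len(self.feature_names)}"
            )
        self.training_keys = list(training_keys) if training_keys is not None else None
        self.n_trees = int(n_trees)
        counts = Counter(self.endog)
        if len(counts) < 2:
            raise ValueError("training requires at least 2 classes")
        if min(counts.values()) < 2:
            raise ValueError("training requires at least 2 observations per class")
        if len(set(counts.values())) != 1 and not allow_unbalanced:
            raise UnbalancedTrainingError(
                f"class counts {dict(counts)} are not balanced; undersample with "
                "balance_training_set() first (or pass allow_unbalanced=True)"
            )
        # label order: default class first, then first appearance
        self.label_set = tuple(
            sorted(counts, key=lambda l: (l != DEFAULT_LABEL, self.endog.index(l)))
        )

    @classmethod
    def from_database(
        cls,
        db,
        exercise: str,
        balance_seed: int | None = 0,
        n_trees: int = DEFAULT_N_TREES,
    ) -> "TechniqueForest":
        """Build the model from a labeled session database.

        The exercise's feature matrix is computed and, unless
        ``balance_seed`` is None, undersampled to class balance.
        """
        matrix, labels, keys = build_feature_matrix(db, exercise)
        if balance_seed is not None:
            keep = balance_training_set(labels, seed=balance_seed)
            matrix = matrix[keep]
            labels = [labels[i] for i in keep]
            keys = [keys[i] for i in keep]
        return cls(
            endog=labels,
            exog=matrix,
            exercise=exercise,
            training_keys=keys,
            n_trees=n_trees,
        )

    def fit(self, seed: int = 0) -> "TechniqueForestResults":
        """Train the ensemble; deterministic given ``seed``."""
        forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            criterion="gini",
            max_features="sqrt",
            bootstrap=True,
            oob_score=True,
            random_state=int(seed),
            n_jobs=1,
        )
        forest.fit(self.exog, self.endog)
        return TechniqueForestResults(self, forest, seed=int(seed))


class TechniqueForestResults:
    """A trained per-exercise technique forest.

    Carries the fitted ensemble, the label set and feature order frozen
    at training time, out-of-bag accuracy as an internal error estimate,
    and the training keys for provenance.
    """

    def __init__(self, model: TechniqueForest, forest: RandomForestClassifier, seed: int):
        self.model = model
        self.forest = forest
        self.seed = seed
        self.exercise = model.exercise
        self.label_set = model.label_set
        self.feature_order = model.feature_names
        self.n_trees = model.n_trees
        self.training_keys = model.training_keys

    # -- diagnostics ----------------------------------------------------

    @property
    def oob_accuracy(self) -> float:
        """Out-of-bag accuracy of the ensemble on its own training set."""
        return float(self.forest.oob_score_)

    @property
    def feature_importances(self) -> dict[str, float]:
        return dict(zip(self.feature_order, self.forest.feature_importances_))

    def summary(self) -> str:
        counts = Counter(self.model.endog)
        lines = [
            "Technique Forest Results",
            "=" * 54,
            f"{'Exercise:':<22}{self.exercise or '<unnamed>'}",
            f"{'No. observations:':<22}{len(self.model.endog)}",
            f"{'Classes:':<22}{', '.join(f'{l} (n={counts[l]})' for l in self.label_set)}",
            f"{'Trees:':<22}{self.n_trees}",
            f"{'Features:':<22}{len(self.feature_order)}",
            f"{'Seed:':<22}{self.seed}",
            f"{'OOB accuracy:':<22}{self.oob_accuracy:.4f}",
            "-" * 54,
            "Top feature importances",
        ]
        top = sorted(self.feature_importances.items(), key=lambda kv: -kv[1])[:10]
        lines += [f"  {name:<38}{value:.4f}" for name, value in top]
        lines.append("=" * 54)
        return "\n".join(lines)

    # -- prediction -----------------------------------------------------

    def _align(self, values: np.ndarray, names) -> np.ndarray:
        names = tuple(names)
        if names == self.feature_order:
            return values
        missing = set(self.feature_order) - set(names)
        extra = set(names) - set(self.feature_order)
        if missing or extra:
            raise ValueError(
                "feature names do not match the model's feature order; "
                f"missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}"
            )
        order = [names.index(n) for n in self.feature_order]
        return values[..., order]

    def predict(self, features, feature_names=None):
        """Predict labels by majority vote over trees.

        ``features`` may be a :class:`FeatureVector`, a 1-D vector in the
        model's feature order, or an (n, 306) matrix.  Returns
        ``(label, vote_fraction)`` for a single vector or
        ``(labels, vote_fractions)`` arrays for a matrix.  Exact vote
        ties break toward the "Acceptable" default class.
        """
        single = False
        if isinstance(features, FeatureVector):
            values = self._align(features.values, features.names)[None, :]
            single = True
        else:
            values = np.asarray(features, dtype=float)
            if values.ndim == 1:
                values = values[None, :]
                single = True
            if feature_names is not None:
                values = self._align(values, feature_names)
            if values.shape[1] != len(self.feature_order):
                raise ValueError(
                    f"expected {len(self.feature_order)} features, got {values.shape[1]}"
                )
        proba = self.forest.predict_proba(values)
        classes = list(self.forest.classes_)
        labels, votes = [], []
        for row in proba:
            best = row.max()
            tied = [classes[i] for i in range(len(classes)) if row[i] == best]
            if DEFAULT_LABEL in tied:
                label = DEFAULT_LABEL
            else:
                label = min(tied, key=self.label_set.index)
            labels.append(label)
            votes.append(float(row[classes.index(label)]))
        if single:
            return labels[0], votes[0]
        return np.asarray(labels), np.asarray(votes)

    # -- auto-label workflow --------------------------------------------

    def auto_label(self, db, keys=None) -> list[AutoLabelProposal]:
        """Propose labels for unlabeled repetitions of this exercise.

        The database is not modified; each proposal must be explicitly
        committed with :func:`accept_proposal` (or dismissed with
        :func:`reject_proposal`, leaving the repetition for manual
        review).
        """
        if keys is None:
            keys = [k for k in db.keys() if k[1] == self.exercise and not db.get(k).labeled]
        proposals = []
        for key in keys:
            rep = db.get(key)
            if rep.exercise != self.exercise:
                raise ValueError(
                    f"repetition {key} is exercise {rep.exercise!r}, "
                    f"model is for {self.exercise!r}"
                )
            label, vote = self.predict(compute_feature_vector(rep))
            proposals.append(AutoLabelProposal(key, label, vote))
        return proposals


def accept_proposal(db, proposal: AutoLabelProposal) -> None:
    """Commit a proposal: the repetition takes the proposed label."""
    db.relabel(proposal.rep_key, proposal.proposed_label)


def reject_proposal(db, proposal: AutoLabelProposal) -> None:
    """Dismiss a proposal: the repetition keeps its default label, stays
    unlabeled, and is queued for manual review."""
    db.mark_for_review(proposal.rep_key)
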