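"""Scikit-learn-style front end to the k-mer HOG classifier.

``HogKmerClassifier`` wraps the fit/predict shape around the pipeline: *fit*
precomputes the evolutionarily informed k-mer table from a reference
database, *predict* assigns query sequences to sub-HOGs.  Hyperparameters
follow sklearn conventions (``get_params``/``set_params``, fitted attributes
with a trailing underscore), so the classifier composes with sklearn model
selection over ``theta_family``/``theta_sub``.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import assignment
from .kmer_table import build_kmer_table
from .reference_db import ReferenceDB


class HogKmerClassifier(ClassifierMixin, BaseEstimator):
    """Alignment-free assignment of proteins to families and sub-HOGs.

    Parameters
    ----------
    k : int, default 6
        k-mer length over the 20-letter canonical alphabet.
    theta_family : float, default 0.05
        Minimum family score; queries below it stay unassigned.
    theta_sub : float, default 0.1
        Minimum per-child subfamily score when descending the HOG tree;
        higher values keep assignments more general.
    top_n_families : int, default 100
        Family scores are computed only for this many candidates with the
        highest raw k-mer hit counts.
    background : {"uniform", "aa_freq"}, default "uniform"
        Chance-hit model for score normalization: uniform ``20**-k`` per
        k-mer, or a probability from reference amino-acid frequencies.

    Attributes
    ----------
    table_ : KmerTable
        The fitted k-mer -> (family, ancestral HOG) table.
    db_ : ReferenceDB
        The reference the table was built from.
    classes_ : ndarray of str
        All assignable HOG ids (plus ``"unassigned"``).
    """

    def __init__(
        self,
        k: int = 6,
        theta_family: float = assignment.DEFAULT_THETA_FAMILY,
        theta_sub: float = assignment.DEFAULT_THETA_SUB,
        top_n_families: int = assignment.DEFAULT_TOP_N_FAMILIES,
        background: str = "uniform",
    ):
        self.k = k
        self.theta_family = theta_family
        self.theta_sub = theta_sub
        self.top_n_families = top_n_families
        self.background = background

    def fit(self, X: ReferenceDB, y=None) -> "HogKmerClassifier":
        """Precompute the k-mer table from a reference database.

        ``X`` is a :class:`~hogmapper.reference_db.ReferenceDB`; labels are
        carried by the database itself (protein -> most specific HOG), so
        ``y`` is ignored.
        """
        if not isinstance(X, ReferenceDB):
            raise TypeError("fit expects a ReferenceDB")
        if self.background not in ("uniform", "aa_freq"):
            raise ValueError(f"unknown background {self.background!r}")
        self.db_ = X
        self.table_ = build_kmer_table(X, k=self.k)
        self.background_p_ = (
            assignment.mean_kmer_hit_probability(X)
            if self.background == "aa_freq"
            else None
        )
        self.classes_ = np.array(sorted(X.hierarchy.hogs) + ["unassigned"])
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "table_"):
            raise AttributeError("this HogKmerClassifier instance is not fitted yet")

    def predict(self, X: Iterable[str]) -> np.ndarray:
        """Assigned sub-HOG id per query sequence (``"unassigned"`` when no
        family passes ``theta_family``)."""
        res = self.assign(X)
        return np.array(
            [r.subfamily_id if r.subfamily_id is not None else "unassigned" for r in res]
        )

    def assign(self, X: Iterable[str] | Iterable[tuple[str, str]]):
        """Full :class:`~hogmapper.assignment.QueryResult` per query."""
        self._check_fitted()
        items = []
        for i, x in enumerate(X):
            if isinstance(x, str):
                items.append((f"q{i + 1}", x))
            else:
                items.append((x[0], x[1]))
        return assignment.search(
            items,
            self.table_,
            theta_family=self.theta_family,
            theta_sub=self.theta_sub,
            top_n=self.top_n_families,
            background_p=self.background_p_,
        )

    def predict_frame(self, X) -> pd.DataFrame:
        """Assignments as a DataFrame (one row per query, input order)."""
        res = self.assign(X)
        return pd.DataFrame(
            {
                "query_id": [r.query_id for r in res],
                "family_id": [r.family_id for r in res],
                "family_score": [r.family_score for r in res],
                "subfamily_id": [r.subfamily_id for r in res],
                "subfamily_score": [r.subfamily_score for r in res],
                "overlap_score": [r.overlap for r in res],
            }
        )
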