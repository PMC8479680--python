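"""Benchmarking: closest-sequence oracle, configuration taxonomy, validation.

The baseline being critiqued is assignment by *closest sequence*: align the
query against every reference protein with exact Smith-Waterman and inherit
the most specific HOG of the best hit.  Relative to the query's true HOG the
closest sequence can sit in four configurations within the family:

- ``true_subfamily`` — same most specific HOG;
- ``over_specific`` — the query's HOG is a strict ancestor of the closest
  sequence's (the baseline guesses too deep);
- ``under_specific`` — the closest sequence's HOG is a strict ancestor of the
  query's (the baseline guesses too shallow);
- ``wrong_path`` — the two HOGs lie on different branches of the family tree.

Validation computes precision/recall/F1 over score thresholds at two levels.
Family level: false positives are negatives placed anywhere plus positives
placed in a wrong family (at or above threshold); positives placed in their
own family split into TP/FN by threshold.  Subfamily level supports two
counting schemes: *implicit*, where an assignment to a sub-HOG also implies
its parental sub-HOGs (per-query TP/FP/FN from the overlap of the predicted
and true root-to-HOG paths, root-HOG excluded), and *stringent*, where only
an exact match earns a TP.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio.alignment import pair_align

from .reference_db import HOGHierarchy, ReferenceDB, is_ancestor

from .reference_db import CANONICAL_ALPHABET


@dataclass(frozen=True)
class AlignmentParams:
    """Smith-Waterman settings.

    Affine gap convention: a gap of length L costs ``gap_open + L *
    gap_extend`` (the BLAST convention).  Penalties are magnitudes (>= 0).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


class ConfigurationLabel(str, enum.Enum):
    TRUE_SUBFAMILY = "true_subfamily"
    OVER_SPECIFIC = "over_specific"
    UNDER_SPECIFIC = "under_specific"
    WRONG_PATH = "wrong_path"


def smith_waterman_score(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Optimal local alignment score (exact affine-gap dynamic programming)."""
    if params is None:
        params = AlignmentParams()
    if not a or not b:
        return 0.0
    res = pair_align(
        a,
        b,
        mode="local",
        sub_score=params.matrix,
        gap_cost=(params.gap_open, params.gap_extend),
        max_paths=0,
    )
    return float(max(res.score, 0.0))


def closest_sequence(
    query: str, db: ReferenceDB, params: AlignmentParams | None = None
) -> tuple[str, float]:
    """Reference protein with the highest Smith-Waterman score to the query.

    Exhaustive by construction; ties break to the smallest protein id, so the
    result is deterministic across runs.
    """
    if not db.proteins:
        raise ValueError("empty reference database")
    best_id, best_score = None, -np.inf
    for pid in sorted(db.proteins):
        s = smith_waterman_score(query, db.proteins[pid].sequence, params)
        if s > best_score:
            best_id, best_score = pid, s
    return best_id, float(best_score)


def classify_configuration(
    true_hog: str, other_hog: str, hierarchy: HOGHierarchy
) -> ConfigurationLabel:
    """Four-way relation between the query's true HOG and another HOG.

    Total, mutually exclusive and exhaustive on same-family pairs; pairs from
    different families are a family-level error and rejected here.
    """
    if hierarchy.family_of(true_hog) != hierarchy.family_of(other_hog):
        raise ValueError(
            f"{true_hog!r} and {other_hog!r} belong to different families"
        )
    if true_hog == other_hog:
        return ConfigurationLabel.TRUE_SUBFAMILY
    if is_ancestor(hierarchy, true_hog, other_hog):
        return ConfigurationLabel.OVER_SPECIFIC
    if is_ancestor(hierarchy, other_hog, true_hog):
        return ConfigurationLabel.UNDER_SPECIFIC
    return ConfigurationLabel.WRONG_PATH


# -- negative query sets -------------------------------------------------


def make_random_negatives(
    aa_freqs: Sequence[float],
    lengths: Sequence[int],
    seed: int,
    id_prefix: str = "neg_rand",
) -> list[tuple[str, str]]:
    """Random protein negatives: i.i.d. residues, lengths of the positives."""
    freqs = np.asarray(aa_freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("amino-acid frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(CANONICAL_ALPHABET.encode(), dtype=np.uint8)
    out = []
    for i, L in enumerate(lengths):
        seq = alphabet[rng.choice(20, size=int(L), p=freqs)].tobytes().decode()
        out.append((f"{id_prefix}{i + 1}", seq))
    return out


def make_clade_negatives(
    donor_db: ReferenceDB, n: int, seed: int
) -> list[tuple[str, str]]:
    """Contamination-style negatives: one protein from each of ``n`` distinct
    donor families (families assumed outside the reference's scope)."""
    rng = np.random.default_rng(seed)
    by_family: dict[str, list[str]] = {}
    for pid, p in donor_db.proteins.items():
        by_family.setdefault(donor_db.hierarchy.family_of(p.hog_id), []).append(pid)
    families = sorted(by_family)
    if len(families) < n:
        raise ValueError(
            f"only {len(families)} donor families available, {n} requested"
        )
    chosen = rng.choice(len(families), size=n, replace=False)
    out = []
    for fi in sorted(chosen):
        fam = families[int(fi)]
        members = sorted(by_family[fam])
        pid = members[int(rng.integers(len(members)))]
        out.append((pid, donor_db.proteins[pid].sequence))
    return out


# -- precision/recall curves ---------------------------------------------


@dataclass
class PRCurve:
    """Threshold-indexed precision/recall/F1 with the F1 optimum."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray

    @property
    def f1_max(self) -> float:
        return float(self.f1.max()) if len(self.f1) else 0.0

    @property
    def threshold_at_f1_max(self) -> float:
        if not len(self.f1):
            return 0.0
        return float(self.thresholds[int(np.argmax(self.f1))])

    @staticmethod
    def from_counts(
        thresholds: Sequence[float],
        tp: Sequence[float],
        fp: Sequence[float],
        fn: Sequence[float],
    ) -> "PRCurve":
        t = np.asarray(thresholds, dtype=float)
        tp = np.asarray(tp, dtype=float)
        fp = np.asarray(fp, dtype=float)
        fn = np.asarray(fn, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
            rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
            f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
        return PRCurve(t, prec, rec, f1)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("threshold\tprecision\trecall\tf1\n")
            for t, p, r, f in zip(self.thresholds, self.precision, self.recall, self.f1):
                fh.write(f"{t:.6f}\t{p:.6f}\t{r:.6f}\t{f:.6f}\n")
            fh.write(
                f"# f1_max={self.f1_max:.6f}\tthreshold={self.threshold_at_f1_max:.6f}\n"
            )


@dataclass(frozen=True)
class FamilyAssignment:
    """One scored family-level call for validation.

    ``family_id`` is None for unassigned queries; ``is_negative`` marks
    members of a negative query set (no true family exists for them).
    """

    query_id: str
    family_id: str | None
    score: float
    is_negative: bool = False


def family_validation(
    results: Sequence[FamilyAssignment],
    truth: Mapping[str, str],
    thresholds: Sequence[float] | None = None,
) -> PRCurve:
    """Family-level PR curve over positives and negatives.

    Per threshold t: FP = negatives assigned with score >= t, plus positives
    assigned to a wrong family with score >= t; positives assigned to their
    own family are TP if score >= t else FN; positives assigned to a wrong
    family below t, or never assigned, count as FN.
    """
    for r in results:
        if r.family_id is not None and r.score is None:
            raise ValueError(f"missing score for assigned query {r.query_id!r}")
    if thresholds is None:
        observed = sorted({r.score for r in results if r.family_id is not None})
        thresholds = observed if observed else [0.0]
    tps, fps, fns = [], [], []
    for t in thresholds:
        tp = fp = fn = 0
        for r in results:
            assigned = r.family_id is not None and r.score >= t
            if r.is_negative:
                fp += assigned
                continue
            correct = r.family_id == truth[r.query_id]
            if assigned and correct:
                tp += 1
            elif assigned:  # wrong family above threshold
                fp += 1
                fn += 1
            else:
                fn += 1
        tps.append(tp)
        fps.append(fp)
        fns.append(fn)
    return PRCurve.from_counts(list(thresholds), tps, fps, fns)


@dataclass(frozen=True)
class SubfamilyPrediction:
    """Threshold-parametric subfamily call for one query.

    ``path_hogs`` are the non-root HOGs of the predicted root-to-HOG path
    (shallow to deep) and ``path_scores`` their acceptance scores: at
    threshold t the effective prediction is the deepest prefix whose scores
    all reach t (empty prefix = the root-HOG).  A fixed single-score method
    (closest sequence) uses its alignment score at every path position, so
    the whole path stands or falls together.
    """

    query_id: str
    family_id: str
    path_hogs: tuple[str, ...]
    path_scores: tuple[float, ...]

    def predicted_at(self, t: float) -> tuple[str, ...]:
        depth = 0
        while depth < len(self.path_hogs) and self.path_scores[depth] >= t:
            depth += 1
        return self.path_hogs[:depth]


def _implicit_counts(
    pred_path: tuple[str, ...], true_path: tuple[str, ...]
) -> tuple[int, int, int]:
    p, t = set(pred_path), set(true_path)
    return len(p & t), len(p - t), len(t - p)


def subfamily_validation(
    results: Sequence[SubfamilyPrediction],
    truth: Mapping[str, str],
    hierarchy: HOGHierarchy,
    mode: str = "implicit",
    thresholds: Sequence[float] | None = None,
) -> PRCurve:
    """Subfamily-level PR curve under implicit or stringent counting.

    ``truth`` maps query ids to true most specific HOGs.  Callers should
    restrict ``results`` to family-level true positives first (placement
    within the family is what is being measured).  Implicit mode credits the
    overlap of predicted and true root-to-HOG paths (root-HOG excluded);
    stringent mode requires an exact match (a root-level prediction with a
    true sub-HOG costs one FN but no FP).
    """
    if mode not in ("implicit", "stringent"):
        raise ValueError(f"unknown mode {mode!r}")
    true_paths: dict[str, tuple[str, ...]] = {}
    for r in results:
        th = truth[r.query_id]
        if th not in hierarchy:
            raise ValueError(f"true HOG {th!r} not in hierarchy")
        if hierarchy.family_of(th) != r.family_id:
            raise ValueError(
                f"prediction for {r.query_id!r} outside its assigned family"
            )
        path = [h for h in reversed(hierarchy.path_to_root(th)) if h != r.family_id]
        true_paths[r.query_id] = tuple(path)
    if thresholds is None:
        observed = sorted({s for r in results for s in r.path_scores})
        thresholds = observed if observed else [0.0]
    tps, fps, fns = [], [], []
    for t in thresholds:
        tp = fp = fn = 0
        for r in results:
            pred = r.predicted_at(t)
            true_path = true_paths[r.query_id]
            if mode == "implicit":
                a, b, c = _implicit_counts(pred, true_path)
                tp += a
                fp += b
                fn += c
            else:
                pred_hog = pred[-1] if pred else r.family_id
                true_hog = true_path[-1] if true_path else r.family_id
                if pred_hog == true_hog:
                    tp += 1
                elif not pred:      # at the root with a true sub-HOG
                    fn += 1
                else:
                    fp += 1
                    fn += 1
        tps.append(tp)
        fps.append(fp)
        fns.append(fn)
    return PRCurve.from_counts(list(thresholds), tps, fps, fns)


# -- closest-sequence configuration survey -------------------------------


@dataclass
class ConfigurationSurvey:
    """Closest-sequence configuration frequencies over a query set.

    Frequencies are over queries whose closest sequence shares their family;
    queries whose closest sequence is in another family are counted apart as
    family-level errors (the configuration taxonomy is within-family only).
    """

    fractions: dict[ConfigurationLabel, float]
    n_same_family: int
    n_other_family: int
    labels: dict[str, ConfigurationLabel | None] = field(default_factory=dict)
    closest: dict[str, str] = field(default_factory=dict)


def configuration_frequencies(
    queries: Iterable[tuple[str, str]],
    db: ReferenceDB,
    truth_hog: Mapping[str, str],
    params: AlignmentParams | None = None,
) -> ConfigurationSurvey:
    """Classify every query's closest reference sequence (Smith-Waterman).

    ``truth_hog`` maps query ids to their true most specific HOG *in the
    reference hierarchy* (leave-one-out callers should pre-project pruned
    HOGs onto the nearest surviving ancestor).
    """
    hierarchy = db.hierarchy
    counts = {label: 0 for label in ConfigurationLabel}
    labels: dict[str, ConfigurationLabel | None] = {}
    closest_of: dict[str, str] = {}
    n_other = 0
    for qid, seq in queries:
        pid, _ = closest_sequence(seq, db, params)
        closest_of[qid] = pid
        true_h = truth_hog[qid]
        close_h = db.proteins[pid].hog_id
        if hierarchy.family_of(true_h) != hierarchy.family_of(close_h):
            n_other += 1
            labels[qid] = None
            continue
        lab = classify_configuration(true_h, close_h, hierarchy)
        counts[lab] += 1
        labels[qid] = lab
    n_same = sum(counts.values())
    fractions = {
        lab: (c / n_same if n_same else 0.0) for lab, c in counts.items()
    }
    return ConfigurationSurvey(fractions, n_same, n_other, labels, closest_of)
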