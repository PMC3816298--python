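"""Spectrum-set selection and fragment binning.

Two distinct questions are answered here. First, *which* spectrum set best
contrasts the organisms expected in a pool: :func:`spectrum_set_test`
profiles the parent genomes under every candidate set and ranks the sets by
how far apart the parents' profiles sit. Second, *how* to split a mixed pool
of fragments: :func:`bin_pool` runs profile -> cluster -> cut(k), and
:func:`iterative_removal` handles pools of three or more organisms by
repeatedly stripping the most contrasting bin (the one whose mean profile is
farthest from the pooled mean) and re-clustering the remainder with the next
set in the schedule — the right schedule head for each round matters because
no single set separates every pair of organisms equally well.

"Contrast" of a realised grouping is formalised as mean silhouette width
(bounded in [-1, 1]; 0 for degenerate groupings). The qualitative notion in
heatmap terms — warm rows against cold rows — has no canonical formula, and
silhouette is the standard metric-consistent choice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_samples

from .clustering import BinAssignment, cluster, cut, distance_matrix, scipy_metric
from .counting import ProfileMatrix, SequenceRecord, profile_matrix
from .spectrum_sets import SEED_NAMES, get_set

logger = logging.getLogger(__name__)

#: Mean-silhouette level below which a binning is flagged as weakly supported.
WEAK_CONTRAST = 0.25


def contrast_score(
    pm: ProfileMatrix,
    labels: Union[Mapping[str, int], Sequence[int]],
    metric: str = "euclidean",
) -> float:
    """Mean silhouette width of a labelled grouping of profile rows.

    Near +1 for tight, well-separated groups; about 0 for labels carved out
    of one homogeneous cloud; negative when rows sit closer to another
    group than their own. Degenerate cases return 0 by convention: all
    pairwise distances zero, or every group a singleton.
    """
    if isinstance(labels, Mapping):
        y = np.array([labels[s] for s in pm.sequence_ids])
    else:
        y = np.asarray(list(labels))
        if len(y) != pm.n_sequences:
            raise ValueError("labels length does not match profile matrix rows")
    groups = np.unique(y)
    if len(groups) < 2:
        raise ValueError("contrast requires at least 2 groups")
    D = distance_matrix(pm, metric)
    if D.max() == 0.0:
        return 0.0
    if len(groups) >= len(y):
        return 0.0  # all-singleton grouping: silhouette is 0 by convention
    s = silhouette_samples(D, y, metric="precomputed")
    return float(np.nan_to_num(s).mean())


@dataclass
class SetSelectionReport:
    """Ranking of candidate spectrum sets by parent-genome separation.

    ``scores[name]`` is the mean pairwise root-mean-square per-motif distance
    between the parents' profile vectors under that set (dividing each
    Euclidean distance by sqrt(set size) keeps 12-motif and 156-motif sets on
    one scale). Ranking is by score descending, ties broken alphabetically.
    """

    scores: Dict[str, float]
    ranking: list[str]
    chosen: str


def spectrum_set_test(
    parents: Sequence[SequenceRecord],
    candidates: Sequence[str] = SEED_NAMES,
    metric: str = "euclidean",
    mode: str = "nonoverlapping",
) -> SetSelectionReport:
    """Rank candidate spectrum sets by how strongly they contrast the parents.

    A base-composition analysis over only the known close relatives of the
    pool's fragments: each parent genome is profiled under each candidate set
    and the sets are ranked by the resulting between-parent separation. Run
    this before binning — choosing the wrong set can erase the contrast
    between two organisms entirely.
    """
    if len(parents) < 2:
        raise ValueError("spectrum_set_test needs at least 2 parent sequences")
    if not candidates:
        raise ValueError("no candidate sets given")
    scores: Dict[str, float] = {}
    for name in candidates:
        sset = get_set(name)
        pm = profile_matrix(parents, sset, mode)
        D = distance_matrix(pm, metric)
        iu = np.triu_indices(len(parents), k=1)
        scores[name] = float(D[iu].mean() / math.sqrt(len(sset)))
    ranking = sorted(scores, key=lambda n: (-scores[n], n))
    return SetSelectionReport(scores=scores, ranking=ranking, chosen=ranking[0])


def bin_pool(
    fragments: Sequence[SequenceRecord],
    set_name: str,
    k: int,
    metric: str = "euclidean",
    linkage: str = "complete",
    mode: str = "nonoverlapping",
) -> BinAssignment:
    """Bin a fragment pool: profile under one spectrum set, cluster, cut at k.

    Returns the assignment together with per-bin mean profiles and the mean
    silhouette contrast of the realised bins (``None`` for k == 1, where
    contrast is undefined).
    """
    if not fragments:
        raise ValueError("empty fragment pool")
    if not 1 <= k <= len(fragments):
        raise ValueError(f"k must be between 1 and {len(fragments)}, got {k}")
    sset = get_set(set_name)
    pm = profile_matrix(fragments, sset, mode)
    if k == 1:
        labels = {s: 1 for s in pm.sequence_ids}
        return BinAssignment(
            labels=labels, k=1, set_name=set_name,
            centroids={1: pm.values.mean(axis=0)}, contrast=None,
        )
    assignment = cut(cluster(pm, metric=metric, linkage=linkage), k)
    assignment.set_name = set_name
    assignment.centroids = {
        b: pm.subset(members).values.mean(axis=0)
        for b, members in assignment.bins().items()
    }
    assignment.contrast = contrast_score(pm, assignment.labels, metric)
    return assignment


@dataclass
class RemovalRound:
    """One round of iterative removal: the k=2 split and the bin stripped."""

    index: int
    set_name: str
    assignment: BinAssignment
    removed_label: int
    removed_ids: list[str]
    remaining_ids: list[str]


@dataclass
class IterativeRemovalResult:
    rounds: list[RemovalRound]
    remainder_ids: list[str]

    def partition(self) -> Dict[str, int]:
        """Final grouping: removed group of round r -> label r; remainder last."""
        out: Dict[str, int] = {}
        for rnd in self.rounds:
            for seq_id in rnd.removed_ids:
                out[seq_id] = rnd.index
        final = len(self.rounds) + 1
        for seq_id in self.remainder_ids:
            out[seq_id] = final
        return out


def iterative_removal(
    fragments: Sequence[SequenceRecord],
    set_schedule: Sequence[str],
    metric: str = "euclidean",
    linkage: str = "complete",
    mode: str = "nonoverlapping",
) -> IterativeRemovalResult:
    """Bin a >=3-organism pool by repeatedly removing the most contrasting bin.

    Each round splits the remaining fragments at k=2 with the next spectrum
    set in the schedule and removes the bin whose mean profile lies farther
    from the pooled mean profile (ties broken toward the smaller bin, then
    the lower bin label). Rounds stop when the schedule is exhausted or at
    most two fragments remain; the final remainder forms the last group. For
    a pool of g organisms a schedule of g-1 sets yields g groups.

    A warning is logged when a round's silhouette contrast falls below
    ``WEAK_CONTRAST`` — removal is then not well supported by the data.
    """
    if not set_schedule:
        raise ValueError("set_schedule must not be empty")
    if len(fragments) < 3:
        raise ValueError("iterative removal needs at least 3 fragments")
    remaining = list(fragments)
    rounds: list[RemovalRound] = []
    for idx, set_name in enumerate(set_schedule, start=1):
        if len(remaining) <= 2:
            break
        assignment = bin_pool(
            remaining, set_name, k=2, metric=metric, linkage=linkage, mode=mode
        )
        if assignment.contrast is not None and assignment.contrast < WEAK_CONTRAST:
            logger.warning(
                "round %d (%s): contrast %.3f is weak; the pool may be "
                "homogeneous and removal unsupported by the data",
                idx, set_name, assignment.contrast,
            )
        pooled = np.vstack([assignment.centroids[b] * len(m)
                            for b, m in assignment.bins().items()])
        sizes = {b: len(m) for b, m in assignment.bins().items()}
        total = sum(sizes.values())
        pooled_centroid = pooled.sum(axis=0, keepdims=True) / total
        sm = scipy_metric(metric)
        dists = {
            b: float(cdist(assignment.centroids[b][None, :], pooled_centroid, metric=sm)[0, 0])
            for b in sizes
        }
        removed = min(sizes, key=lambda b: (-dists[b], sizes[b], b))
        removed_ids = [s for s in (f.id for f in remaining)
                       if assignment.labels[s] == removed]
        remaining = [f for f in remaining if assignment.labels[f.id] != removed]
        rounds.append(RemovalRound(
            index=idx, set_name=set_name, assignment=assignment,
            removed_label=removed, removed_ids=removed_ids,
            remaining_ids=[f.id for f in remaining],
        ))
    return IterativeRemovalResult(rounds=rounds, remainder_ids=[f.id for f in remaining])
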