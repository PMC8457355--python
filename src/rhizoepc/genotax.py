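"""Genome-context classification.

Three classifications used to interpret EPC associations:

* genospecies — fragment-based average nucleotide identity (ANI):
  genomes are chopped into 1020-bp fragments, each locally aligned to
  the partner genome, retained when identity > 30% over >= 70% of the
  fragment, and averaged; clusters are connected components of the
  >= 95%-ANI graph (single linkage), with distant strains flagged below
  a secondary outlier threshold;
* nodulation types/groups — p-distances over pre-aligned concatenated
  nodulation-gene sequences, neighbor-joining for display, and nested
  single-linkage cuts (coarse clusters = Nod types, fine = Nod groups);
* plasmid replicon (Rh) groups — best repA similarity picks the
  candidate class, assigned only when the cognate repB and repC are also
  present on the replicon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from ._dna import seq_to_array
from .assoc import check_presence, local_align

from typing import Mapping


# ---------------------------------------------------------------------------
# ANI and genospecies
# ---------------------------------------------------------------------------

FRAGMENT_LENGTH = 1020
FRAGMENT_MIN_IDENTITY = 0.30
FRAGMENT_MIN_COVERAGE = 0.70


def _one_way_ani(genome_a: str, genome_b: str, fragment_length: int) -> float | None:
    """Mean identity (fraction) of retained fragments of A aligned to B,
    or None when no fragment is retained."""
    identities = []
    for start in range(0, len(genome_a) - fragment_length + 1, fragment_length):
        frag = genome_a[start:start + fragment_length]
        hit = local_align(frag, genome_b)
        if hit is None:
            continue
        if hit.identity > FRAGMENT_MIN_IDENTITY and \
                hit.coverage >= FRAGMENT_MIN_COVERAGE:
            identities.append(hit.identity)
    if not identities:
        return None
    return float(np.mean(identities))


def pairwise_ani(genome_a: str, genome_b: str,
                 fragment_length: int = FRAGMENT_LENGTH) -> float:
    """Symmetrised fragment-based ANI percentage (mean of both one-way
    values).  Undefined pairs (no retained fragment) return NaN."""
    if len(genome_a) < fragment_length or len(genome_b) < fragment_length:
        raise ValueError("genomes must be at least one fragment long")
    ab = _one_way_ani(genome_a, genome_b, fragment_length)
    ba = _one_way_ani(genome_b, genome_a, fragment_length)
    vals = [v for v in (ab, ba) if v is not None]
    if not vals:
        return float("nan")
    return 100.0 * float(np.mean(vals))


def ani_matrix(genomes: Mapping[str, str],
               fragment_length: int = FRAGMENT_LENGTH) -> pd.DataFrame:
    """Symmetric ANI percentage matrix with diagonal exactly 100."""
    ids = sorted(genomes)
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            v = pairwise_ani(genomes[a], genomes[b], fragment_length)
            mat.loc[a, b] = mat.loc[b, a] = v
    return mat


def assign_genospecies(ani: pd.DataFrame, threshold: float = 95.0,
                       outlier_threshold: float = 92.0
                       ) -> tuple[pd.Series, pd.Series]:
    """Single-linkage genospecies clusters at the ANI threshold.

    Returns ``(labels, outside_complex)``: components of the graph with
    edges where ANI >= threshold, labelled gs1, gs2, ... by decreasing
    size (ties by smallest member), plus a flag for strains whose best
    off-diagonal ANI is below ``outlier_threshold``.
    """
    if ani.isna().any().any():
        raise ValueError("missing ANI pairs")
    if not np.allclose(ani.to_numpy(), ani.to_numpy().T):
        raise ValueError("ANI matrix must be symmetric")
    ids = list(ani.index)
    from scipy.sparse.csgraph import connected_components
    adj = (ani.to_numpy() >= threshold).astype(int)
    n_comp, comp = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for sid, c in zip(ids, comp):
        groups.setdefault(int(c), []).append(sid)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), sorted(g)[0]))
    labels = pd.Series(index=ids, dtype=object)
    for rank, members in enumerate(ordered, start=1):
        labels[members] = f"gs{rank}"
    off = ani.to_numpy().copy()
    np.fill_diagonal(off, -np.inf)
    outside = pd.Series(off.max(axis=1) < outlier_threshold, index=ids)
    return labels, outside


# ---------------------------------------------------------------------------
# nod gene phylogeny
# ---------------------------------------------------------------------------

def p_distance(aligned: Mapping[str, str]) -> pd.DataFrame:
    """Pairwise mismatch fraction over sites without a gap in either
    sequence; zero comparable sites raise."""
    ids = sorted(aligned)
    lengths = {len(aligned[i]) for i in ids}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    arr = np.vstack([seq_to_array(aligned[i]) for i in ids])
    gap = arr == ord("-")
    n = len(ids)
    out = pd.DataFrame(0.0, index=ids, columns=ids)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            sites = int(ok.sum())
            if sites == 0:
                raise ValueError(f"zero comparable sites between "
                                 f"{ids[i]} and {ids[j]}")
            d = float((arr[i, ok] != arr[j, ok]).sum()) / sites
            out.iloc[i, j] = out.iloc[j, i] = d
    return out


@dataclass
class NodPhylogeny:
    """Unrooted NJ tree over nodulation-gene distances, with per-strain
    type/group labels attached."""

    tree: TreeNode
    nod_type: pd.Series
    nod_group: pd.Series


def nj_tree(distance_matrix: pd.DataFrame, outgroup: str | None = None) -> TreeNode:
    """Canonical neighbor joining; deterministic via sorted label order.
    Negative branch-length estimates are clamped to zero.  ``outgroup``
    reroots the returned tree for display."""
    d = distance_matrix
    if not np.allclose(d.to_numpy(), d.to_numpy().T):
        raise ValueError("distance matrix must be symmetric")
    if d.shape[0] < 3:
        raise ValueError("need at least three taxa")
    ids = sorted(d.index)
    dm = DistanceMatrix(d.loc[ids, ids].to_numpy(), ids=ids)
    tree = nj(dm, neg_as_zero=True)
    if outgroup is not None:
        tree = tree.root_at(tree.find(outgroup).parent)
    return tree


def assign_nod_groups(distance_matrix: pd.DataFrame,
                      type_cut: float = 0.10,
                      group_cut: float = 0.03) -> pd.DataFrame:
    """Nested single-linkage cuts of the nod p-distance matrix.

    Coarse clusters at ``type_cut`` are Nod types (A, B, ... by
    decreasing size), fine clusters at ``group_cut`` are Nod groups
    (A1, A2, ... within each type); single linkage makes the fine
    partition refine the coarse one.  A single coarse cluster warns but
    labels are still emitted.
    """
    if not group_cut < type_cut:
        raise ValueError("need group_cut < type_cut")
    ids = sorted(distance_matrix.index)
    d = distance_matrix.loc[ids, ids]
    condensed = squareform(d.to_numpy(), checks=False)
    link = hierarchy.linkage(condensed, method="single")
    coarse = hierarchy.fcluster(link, t=type_cut, criterion="distance")
    fine = hierarchy.fcluster(link, t=group_cut, criterion="distance")
    if len(set(coarse)) == 1:
        import warnings
        warnings.warn("type_cut yields a single coarse cluster", stacklevel=2)

    def order_labels(assign: np.ndarray) -> list[list[str]]:
        groups: dict[int, list[str]] = {}
        for sid, c in zip(ids, assign):
            groups.setdefault(int(c), []).append(sid)
        return sorted(groups.values(), key=lambda g: (-len(g), sorted(g)[0]))

    type_label = {}
    for rank, members in enumerate(order_labels(coarse)):
        for sid in members:
            type_label[sid] = chr(ord("A") + rank)
    group_label = {}
    by_type: dict[str, list[list[str]]] = {}
    for members in order_labels(fine):
        t = type_label[members[0]]
        by_type.setdefault(t, []).append(members)
    for t, clusters in by_type.items():
        for idx, members in enumerate(clusters, start=1):
            for sid in members:
                group_label[sid] = f"{t}{idx}"
    return pd.DataFrame({"nod_type": pd.Series(type_label),
                         "nod_group": pd.Series(group_label)}).loc[ids]


def nod_phylogeny(aligned: Mapping[str, str], type_cut: float = 0.10,
                  group_cut: float = 0.03,
                  outgroup: str | None = None) -> NodPhylogeny:
    """NJ tree plus type/group labels from one aligned input."""
    d = p_distance(aligned)
    tree = nj_tree(d, outgroup=outgroup)
    labels = assign_nod_groups(d, type_cut=type_cut, group_cut=group_cut)
    return NodPhylogeny(tree=tree, nod_type=labels["nod_type"],
                        nod_group=labels["nod_group"])


# ---------------------------------------------------------------------------
# replicon (Rh group) classification
# ---------------------------------------------------------------------------

@dataclass
class RepliconCall:
    replicon_id: str
    rh_group: str | None
    repa_identity: float
    repb_found: bool
    repc_found: bool
    tie: bool = False
    reason: str = ""


def classify_replicon(replicon_seq: str,
                      repa_references: Mapping[str, str],
                      repb_reference: str,
                      repc_reference: str,
                      similarity_floor: float = 0.70,
                      replicon_id: str = "replicon") -> RepliconCall:
    """Rh-group call: the best repA hit names the candidate class (when
    its identity exceeds ``similarity_floor``), and the class is assigned
    only if cognate repB and repC are both present; otherwise the call is
    unclassified with the reasons recorded.  Score ties resolve to the
    lexicographically smallest Rh label and set ``tie``."""
    if not repa_references:
        raise ValueError("repA reference set must be non-empty")
    scored: list[tuple[int, str, float]] = []
    for label in sorted(repa_references):
        hit = local_align(repa_references[label], replicon_seq)
        if hit is not None:
            scored.append((hit.score, label, hit.identity))
    if not scored:
        return RepliconCall(replicon_id, None, 0.0, False, False,
                            reason="no repA hit")
    best_score = max(s for s, _, _ in scored)
    top = [t for t in scored if t[0] == best_score]
    _, label, identity = min(top, key=lambda t: t[1])
    tie = len(top) > 1
    if identity <= similarity_floor:
        return RepliconCall(replicon_id, None, identity, False, False, tie,
                            reason="repA below similarity floor")
    repb = check_presence(repb_reference, replicon_seq)
    repc = check_presence(repc_reference, replicon_seq)
    if repb and repc:
        return RepliconCall(replicon_id, label, identity, True, True, tie)
    missing = [n for n, found in (("repB", repb), ("repC", repc)) if not found]
    return RepliconCall(replicon_id, None, identity, repb, repc, tie,
                        reason=f"missing cognate genes: {'+'.join(missing)}")
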