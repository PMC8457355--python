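"""Genotype-phenotype association for EPC.

Two routes from strain classifications and gene content to the EPC
phenotype:

* nonparametric tests — Kruskal-Wallis across factor levels
  (genospecies, Nod type, Nod group, or gene presence), followed by a
  Dunn post hoc with Bonferroni correction and a compact letter display;
* a presence/absence contrast — genes carried by every one of the k
  highest-EPC strains and by none of the k lowest (or the reverse) are
  candidates, then validated across all detected strains.

Gene presence is called with a hand-rolled ungapped seed-and-extend
local aligner (exact k-mer seeds, x-drop extension): a contract-level
stand-in for a full aligner, adequate because presence calls use
coarse identity/coverage thresholds (strictly >70% / >70%).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._dna import seq_to_array

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PresenceMatrix:
    """strains x genes boolean matrix plus the thresholds that made it."""

    matrix: pd.DataFrame
    identity_threshold: float = 0.70
    coverage_threshold: float = 0.70
    provenance: str = "similarity_search"

    def __post_init__(self) -> None:
        for t in (self.identity_threshold, self.coverage_threshold):
            if not 0 < t <= 1:
                raise ValueError("thresholds must be in (0, 1]")
        if self.matrix.isna().any().any():
            raise ValueError("presence matrix must be complete")


@dataclass
class AssociationResult:
    host: str
    factor: str
    H: float
    p: float
    letters: dict[str, str] | None = None
    medians: dict[str, float] = field(default_factory=dict)
    n: dict[str, int] = field(default_factory=dict)
    note: str = ""


@dataclass
class ContrastCandidate:
    gene_id: str
    host: str
    direction: str                  # "present_in_top" | "absent_in_top"
    top_set: list[str] = field(default_factory=list)
    bottom_set: list[str] = field(default_factory=list)
    validation_p: float | None = None


@dataclass(frozen=True)
class LocalHit:
    score: int
    identity: float
    coverage: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def _rank_stat(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    """Tie-corrected H for integer group codes 0..k-1."""
    n = values.size
    ranks = stats.rankdata(values)
    h = 0.0
    for g in range(k):
        r = ranks[codes == g]
        h += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    if tie == 0.0:       # all observations identical
        return 0.0
    return h / tie


def kruskal_wallis(values: Sequence[float], group_labels: Sequence,
                   method: str = "chi2") -> tuple[float, float]:
    """Kruskal-Wallis H and p value.

    ``method="chi2"`` uses the chi-square approximation with k-1 degrees
    of freedom; ``method="exact"`` enumerates every distinct assignment
    of the group labels to the observations (feasible for small N) and
    returns P(H_perm >= H_obs).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.size != labels.size:
        raise ValueError("values and group_labels differ in length")
    uniq, codes = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValueError("need at least two groups")
    if values.size < 3:
        raise ValueError("need at least three observations")
    h = _rank_stat(values, codes, k)
    if np.allclose(h, 0.0) and np.unique(values).size == 1:
        return 0.0, 1.0
    if method == "chi2":
        return float(h), float(stats.chi2.sf(h, k - 1))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    # full enumeration over distinct label assignments
    counts = [int((codes == g).sum()) for g in range(k)]
    n = values.size
    hits = 0
    total = 0
    positions = list(range(n))

    def recurse(remaining: list[int], group: int, assignment: np.ndarray):
        nonlocal hits, total
        if group == k - 1:
            assignment[remaining] = group
            total += 1
            if _rank_stat(values, assignment, k) >= h - 1e-12:
                hits += 1
            return
        for chosen in itertools.combinations(remaining, counts[group]):
            assignment[list(chosen)] = group
            rest = [i for i in remaining if i not in set(chosen)]
            recurse(rest, group + 1, assignment)

    recurse(positions, 0, np.zeros(n, dtype=np.int64))
    return float(h), hits / total


# ---------------------------------------------------------------------------
# Dunn post hoc with compact letter display
# ---------------------------------------------------------------------------

def _compact_letters(levels: Sequence[str], medians: Mapping[str, float],
                     significant: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-absorb compact letter display over median-sorted groups:
    two groups share a letter iff their pair is not significant."""
    order = sorted(levels, key=lambda g: (-medians[g], g))
    letter_sets: list[set[str]] = [set(order)]
    for i, j in significant:
        for s in list(letter_sets):
            if i in s and j in s:
                letter_sets.remove(s)
                a, b = s - {i}, s - {j}
                for new in (a, b):
                    if new and not any(new <= other for other in letter_sets):
                        letter_sets.append(new)
        letter_sets = [s for s in letter_sets
                       if not any(s < other for other in letter_sets)]
    letter_sets.sort(key=lambda s: min(order.index(g) for g in s))
    out: dict[str, str] = {g: "" for g in levels}
    for idx, s in enumerate(letter_sets):
        ch = chr(ord("a") + idx)
        for g in order:
            if g in s:
                out[g] += ch
    return out


def dunn_posthoc(values: Sequence[float], group_labels: Sequence,
                 alpha: float = 0.05):
    """Pairwise Dunn z tests on ranks, Bonferroni-adjusted, plus a
    compact letter display.

    Returns ``(p_adjusted, z, letters)`` where the first two are
    DataFrames over group levels.  z uses the tie-corrected pooled
    variance N(N+1)/12 - sum(t^3-t)/(12(N-1)).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels, dtype=object)
    levels = sorted(set(labels.tolist()))
    if any((labels == g).sum() == 0 for g in levels):
        raise ValueError("empty group")
    n = values.size
    ranks = stats.rankdata(values)
    mean_rank = {g: ranks[labels == g].mean() for g in levels}
    sizes = {g: int((labels == g).sum()) for g in levels}
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    pooled = n * (n + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(levels, 2))
    z = pd.DataFrame(np.nan, index=levels, columns=levels)
    padj = pd.DataFrame(np.nan, index=levels, columns=levels)
    m = len(pairs)
    for i, j in pairs:
        denom = np.sqrt(pooled * (1.0 / sizes[i] + 1.0 / sizes[j]))
        zij = 0.0 if denom == 0 else (mean_rank[i] - mean_rank[j]) / denom
        praw = 2.0 * stats.norm.sf(abs(zij))
        p = min(1.0, praw * m)
        z.loc[i, j] = z.loc[j, i] = zij
        padj.loc[i, j] = padj.loc[j, i] = p
    medians = {g: float(np.median(values[labels == g])) for g in levels}
    significant = {(i, j) for i, j in pairs if padj.loc[i, j] < alpha}
    letters = _compact_letters(levels, medians, significant)
    return padj, z, letters


# ---------------------------------------------------------------------------
# species pooling and factor association
# ---------------------------------------------------------------------------

def pool_species(epc_mean: pd.DataFrame,
                 cultivar_to_species: Mapping[str, str]) -> pd.DataFrame:
    """Stack strain x cultivar mean EPC cells into per-species
    observations (each cell is one observation, so a species with c
    cultivars contributes n_strains * c values)."""
    unmapped = [c for c in epc_mean.columns if c not in cultivar_to_species]
    if unmapped:
        raise ValueError(f"unmapped cultivars: {unmapped}")
    long = (epc_mean.rename_axis(index="strain_id", columns="cultivar")
            .stack().rename("epc").reset_index())
    long["species"] = long["cultivar"].map(cultivar_to_species)
    return long


def associate_factor(epc_mean: pd.DataFrame, factor: Mapping[str, str] | pd.Series,
                     host: str, factor_name: str = "factor",
                     alpha: float = 0.05,
                     observations: pd.DataFrame | None = None) -> AssociationResult:
    """Kruskal-Wallis (and Dunn letters when >2 levels) of EPC against a
    strain classification, on one host column or on pooled observations
    (a DataFrame with columns strain_id and epc)."""
    factor = pd.Series(dict(factor)) if not isinstance(factor, pd.Series) else factor
    if observations is None:
        obs = pd.DataFrame({"strain_id": epc_mean.index,
                            "epc": epc_mean[host].to_numpy()})
    else:
        obs = observations
    obs = obs.assign(level=obs["strain_id"].map(factor)).dropna(subset=["level"])
    h, p = kruskal_wallis(obs["epc"].to_numpy(), obs["level"].to_numpy())
    levels = sorted(set(obs["level"]))
    letters = None
    if len(levels) >= 2:
        _, _, letters = dunn_posthoc(obs["epc"].to_numpy(),
                                     obs["level"].to_numpy(), alpha=alpha)
    medians = {g: float(obs.loc[obs["level"] == g, "epc"].median()) for g in levels}
    sizes = {g: int((obs["level"] == g).sum()) for g in levels}
    return AssociationResult(host=host, factor=factor_name, H=h, p=p,
                             letters=letters, medians=medians, n=sizes)


# ---------------------------------------------------------------------------
# ranking and presence/absence contrast
# ---------------------------------------------------------------------------

def rank_strains(epc_mean: pd.DataFrame, host: str,
                 totals: pd.Series | None = None) -> list[str]:
    """Strains ordered by descending mean EPC on ``host``; ties broken
    by descending total reads, then by label."""
    if host not in epc_mean.columns:
        raise KeyError(f"unknown host {host!r}")
    col = epc_mean[host]
    tot = totals.reindex(epc_mean.index).fillna(0.0) if totals is not None \
        else pd.Series(0.0, index=epc_mean.index)
    order = sorted(epc_mean.index, key=lambda s: (-col[s], -tot[s], s))
    return order


def contrast_genes(ranked_strains: Sequence[str],
                   presence_matrix: PresenceMatrix | pd.DataFrame,
                   k_top: int = 5, k_bottom: int = 5,
                   host: str = "") -> list[ContrastCandidate]:
    """Genes present in every top-k strain and absent from every
    bottom-k strain, or the reverse.

    ``ranked_strains`` may already be restricted to a subgroup (for
    screens within, e.g., the nodX carriers).
    """
    matrix = presence_matrix.matrix if isinstance(presence_matrix, PresenceMatrix) \
        else presence_matrix
    ranked = list(ranked_strains)
    if k_top + k_bottom > len(ranked):
        raise ValueError("k_top + k_bottom exceeds the number of strains")
    top = ranked[:k_top]
    bottom = ranked[-k_bottom:]
    if set(top) & set(bottom):
        raise ValueError("top and bottom sets overlap")
    candidates = []
    sub = matrix.loc[top + bottom]
    for gene in matrix.columns:
        in_top = sub.loc[top, gene]
        in_bottom = sub.loc[bottom, gene]
        if in_top.all() and not in_bottom.any():
            direction = "present_in_top"
        elif not in_top.any() and in_bottom.all():
            direction = "absent_in_top"
        else:
            continue
        candidates.append(ContrastCandidate(gene_id=gene, host=host,
                                            direction=direction,
                                            top_set=list(top),
                                            bottom_set=list(bottom)))
    return candidates


def validate_candidates(candidates: Sequence[ContrastCandidate],
                        epc_mean: pd.DataFrame,
                        presence_matrix: PresenceMatrix | pd.DataFrame
                        ) -> list[AssociationResult]:
    """Kruskal-Wallis of EPC between carriers and non-carriers of each
    candidate gene over all detected strains (per candidate host)."""
    matrix = presence_matrix.matrix if isinstance(presence_matrix, PresenceMatrix) \
        else presence_matrix
    results = []
    for cand in candidates:
        if cand.gene_id not in matrix.columns:
            raise KeyError(f"candidate gene {cand.gene_id!r} not in matrix")
        strains = [s for s in epc_mean.index if s in matrix.index]
        carrier = matrix.loc[strains, cand.gene_id].astype(bool)
        sizes = {True: int(carrier.sum()), False: int((~carrier).sum())}
        if 0 in sizes.values():
            results.append(AssociationResult(
                host=cand.host, factor=cand.gene_id, H=np.nan, p=np.nan,
                n={"carrier": sizes[True], "noncarrier": sizes[False]},
                note="gene fixed in all strains: validation undefined"))
            continue
        if min(sizes.values()) == 1:
            warnings.warn(f"{cand.gene_id}: a presence class has a single "
                          "strain; validation power is minimal", stacklevel=2)
        values = epc_mean.loc[strains, cand.host].to_numpy()
        h, p = kruskal_wallis(values, carrier.to_numpy())
        cand.validation_p = p
        results.append(AssociationResult(
            host=cand.host, factor=cand.gene_id, H=h, p=p,
            medians={"carrier": float(epc_mean.loc[strains, cand.host][carrier].median()),
                     "noncarrier": float(epc_mean.loc[strains, cand.host][~carrier].median())},
            n={"carrier": sizes[True], "noncarrier": sizes[False]}))
    return results


# ---------------------------------------------------------------------------
# ungapped seed-and-extend local alignment
# ---------------------------------------------------------------------------

MATCH_SCORE = 1
MISMATCH_SCORE = -2


@lru_cache(maxsize=16)
def _kmer_index(subject: str, k: int) -> dict:
    index: dict[str, list[int]] = {}
    for i in range(len(subject) - k + 1):
        index.setdefault(subject[i:i + k], []).append(i)
    return index


def _extend(eq: np.ndarray, xdrop: int) -> tuple[int, int]:
    """Best x-drop extension over a boolean match vector.

    Returns ``(length, score)`` of the prefix achieving the maximum
    cumulative score before the running drop exceeds ``xdrop``.
    """
    if eq.size == 0:
        return 0, 0
    scores = np.where(eq, MATCH_SCORE, MISMATCH_SCORE).cumsum()
    running_max = np.maximum.accumulate(np.maximum(scores, 0))
    dropped = np.nonzero(running_max - scores > xdrop)[0]
    stop = dropped[0] if dropped.size else eq.size
    if stop == 0:
        return 0, 0
    best = int(np.argmax(scores[:stop]))
    if scores[best] <= 0:
        return 0, 0
    return best + 1, int(scores[best])


def local_align(query: str, subject: str, seed_k: int = 11,
                xdrop: int = 20) -> LocalHit | None:
    """Best ungapped local hit by exact k-mer seeding and two-way x-drop
    extension; ``None`` when no seed matches.

    One extension per diagonal (from its first seed).  Identity is
    matches / alignment length, coverage is alignment length / query
    length; ties on score resolve to the smallest subject position.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    if len(query) < seed_k:
        raise ValueError("query shorter than seed length")
    index = _kmer_index(subject, seed_k)
    q_arr = seq_to_array(query)
    s_arr = seq_to_array(subject)
    seen_diagonals: set[int] = set()
    best: LocalHit | None = None
    for qpos in range(len(query) - seed_k + 1):
        for spos in index.get(query[qpos:qpos + seed_k], ()):
            diag = spos - qpos
            if diag in seen_diagonals:
                continue
            seen_diagonals.add(diag)
            max_right = min(len(query) - qpos, len(subject) - spos) - seed_k
            right = (q_arr[qpos + seed_k:qpos + seed_k + max_right] ==
                     s_arr[spos + seed_k:spos + seed_k + max_right])
            left_len = min(qpos, spos)
            left = (q_arr[qpos - left_len:qpos] ==
                    s_arr[spos - left_len:spos])[::-1]
            r_len, r_score = _extend(right, xdrop)
            l_len, l_score = _extend(left, xdrop)
            q0, q1 = qpos - l_len, qpos + seed_k + r_len
            s0 = spos - l_len
            aln_len = q1 - q0
            matches = int((q_arr[q0:q1] == s_arr[s0:s0 + aln_len]).sum())
            hit = LocalHit(score=seed_k + r_score + l_score,
                           identity=matches / aln_len,
                           coverage=aln_len / len(query),
                           query_start=q0, query_end=q1,
                           subject_start=s0, subject_end=s0 + aln_len)
            if best is None or (hit.score, -hit.subject_start) > \
                    (best.score, -best.subject_start):
                best = hit
    return best


def check_presence(gene_seq: str, genome_seq: str,
                   identity_threshold: float = 0.70,
                   coverage_threshold: float = 0.70,
                   seed_k: int = 11, xdrop: int = 20) -> bool:
    """True iff the best local hit strictly exceeds both the identity
    and the coverage threshold."""
    for t in (identity_threshold, coverage_threshold):
        if not 0 < t <= 1:
            raise ValueError("thresholds must be in (0, 1]")
    hit = local_align(gene_seq, genome_seq, seed_k=seed_k, xdrop=xdrop)
    if hit is None:
        return False
    return hit.identity > identity_threshold and hit.coverage > coverage_threshold


def presence_matrix_from_genomes(gene_sequences: Mapping[str, str],
                                 genomes: Mapping[str, str],
                                 identity_threshold: float = 0.70,
                                 coverage_threshold: float = 0.70
                                 ) -> PresenceMatrix:
    """Presence/absence calls of every gene in every genome."""
    matrix = pd.DataFrame(
        {g: {s: check_presence(seq, genomes[s], identity_threshold,
                               coverage_threshold)
             for s in genomes}
         for g, seq in gene_sequences.items()})
    return PresenceMatrix(matrix=matrix,
                          identity_threshold=identity_threshold,
                          coverage_threshold=coverage_threshold)


def bidirectional_best_hits(geneset_a: Mapping[str, str],
                            geneset_b: Mapping[str, str],
                            seed_k: int = 11, xdrop: int = 20
                            ) -> list[tuple[str, str]]:
    """Reciprocal best-scoring hits between two gene sets (ties broken
    by label); genes without a qualifying hit stay unpaired."""
    if not geneset_a or not geneset_b:
        raise ValueError("gene sets must be non-empty")

    def best_hits(src: Mapping[str, str], dst: Mapping[str, str]) -> dict[str, str]:
        out = {}
        for name, seq in src.items():
            scored = []
            for other, other_seq in dst.items():
                hit = local_align(seq, other_seq, seed_k=seed_k, xdrop=xdrop)
                if hit is not None:
                    scored.append((-hit.score, other))
            if scored:
                out[name] = min(scored)[1]
        return out

    a_best = best_hits(geneset_a, geneset_b)
    b_best = best_hits(geneset_b, geneset_a)
    return sorted((a, b) for a, b in a_best.items() if b_best.get(b) == a)
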