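"""Synthetic data generation with full ground truth.

This module emulates a mixed-inoculation metabarcoding experiment on
nodulated legume roots: a panel of rhizobial strains distinguished by a
fixed-length marker-gene barcode, host-specific nodulation propensities
driven by planted gene-presence effects, and Illumina-style paired-end
amplicon reads with substitution errors and phred+33 qualities.  Every
generator returns the truth needed to test the downstream pipeline
(barcode design, exact-match quantification, EPC statistics, gene
association, genome taxonomy) without any external data.

The stated world of the defaults mirrors the experiment the package
models: 32 strains with 309-bp barcode alleles behind conserved 20-bp
primer sites, 9 host genotypes x 4 biological replicates, ~14,203 read
pairs per sample from a 2 x 250 bp protocol, and 6-bp sample tags.
"""

from __future__ import annotations

import json
import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._dna import (
    mutate,
    phred_error_prob,
    quals_to_string,
    random_dna,
    revcomp,
    seq_to_array,
)

# Fixed default primer pair flanking the barcode window (20 bp each, the
# window itself is 309 bp).  Arbitrary but constant: tests and the CLI rely
# on reproducible defaults, not on primer thermodynamics.
DEFAULT_PRIMER_FWD = "ATGCGTATTGGGCAACGAGT"
DEFAULT_PRIMER_REV = "TGGTCAACGTCATTGCGAGA"
DEFAULT_TAG_LENGTH = 6


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Strain:
    id: str
    marker_sequence: str


@dataclass
class StrainPanel:
    """A strain collection plus the primer pair that brackets its barcode.

    ``marker_sequence`` of each strain contains exactly one occurrence of
    ``primer_fwd`` and of ``revcomp(primer_rev)``; the window between them
    is the barcode allele (``allele_length`` bp).
    """

    strains: list[Strain]
    primer_fwd: str
    primer_rev: str
    allele_length: int

    @property
    def strain_ids(self) -> list[str]:
        return [s.id for s in self.strains]

    def allele_of(self, strain: Strain) -> str:
        seq = strain.marker_sequence
        start = seq.index(self.primer_fwd) + len(self.primer_fwd)
        end = seq.index(revcomp(self.primer_rev))
        return seq[start:end]

    @property
    def alleles(self) -> dict[str, str]:
        """strain_id -> barcode allele sequence."""
        return {s.id: self.allele_of(s) for s in self.strains}

    @property
    def amplicons(self) -> dict[str, str]:
        """strain_id -> full amplicon (fwd primer + allele + rc rev primer)."""
        rc = revcomp(self.primer_rev)
        return {sid: self.primer_fwd + allele + rc
                for sid, allele in self.alleles.items()}

    def truth_membership(self) -> dict[str, list[str]]:
        """allele sequence -> sorted strain ids carrying it."""
        members: dict[str, list[str]] = {}
        for sid, allele in self.alleles.items():
            members.setdefault(allele, []).append(sid)
        return {a: sorted(m) for a, m in members.items()}


@dataclass
class TruthMixture:
    """True strain composition of one sample (host x replicate)."""

    host_genotype: str
    replicate: int
    proportions: dict[str, float]
    depth: int

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, expected 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass(frozen=True)
class PlantedEffect:
    """Multiplicative nodulation-propensity effect of carrying a gene.

    ``effect_size`` multiplies the propensity of carrier strains on
    ``host_genotype``; 1 means a null gene.
    """

    gene_id: str
    host_genotype: str
    effect_size: float

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass
class PangenomeTruth:
    """Output bundle of :func:`simulate_pangenome`."""

    presence: pd.DataFrame                  # strains x genes, bool
    gene_sequences: dict[str, str]
    genomes: dict[str, str]
    planted_genes: list[str]
    replicons: dict[str, str]
    rh_truth: dict[str, str]
    repa_references: dict[str, str]
    repb_reference: str
    repc_reference: str
    genospecies_truth: dict[str, str]


@dataclass(frozen=True)
class QualityModel:
    """Two-state quality model: most bases at ``q_high``, an error-prone
    minority at ``q_low``; per-base error probability is 10^(-Q/10)."""

    q_high: int = 38
    q_low: int = 7

    def low_fraction(self, error_rate: float) -> float:
        p_high = 10.0 ** (-self.q_high / 10.0)
        p_low = 10.0 ** (-self.q_low / 10.0)
        if error_rate <= p_high:
            return 0.0
        return (error_rate - p_high) / (p_low - p_high)


@dataclass
class ReadBatch:
    """Equal-length paired reads of one sample as ASCII-code arrays."""

    sample_id: str
    r1_seq: np.ndarray      # (n_reads, L1) uint8
    r1_qual: np.ndarray     # phred scores, int
    r2_seq: np.ndarray
    r2_qual: np.ndarray
    strain_truth: list[str] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return self.r1_seq.shape[0]

    def iter_pairs(self) -> Iterable[tuple[str, str, str, str]]:
        for i in range(self.n_reads):
            yield (self.r1_seq[i].tobytes().decode(),
                   quals_to_string(self.r1_qual[i]),
                   self.r2_seq[i].tobytes().decode(),
                   quals_to_string(self.r2_qual[i]))

    def to_fastq(self, path_r1, path_r2, gzip_output: bool | None = None) -> None:
        """Write the pair of FASTQ files (phred+33)."""
        for path, seqs, quals in ((path_r1, self.r1_seq, self.r1_qual),
                                  (path_r2, self.r2_seq, self.r2_qual)):
            path = Path(path)
            use_gz = path.suffix == ".gz" if gzip_output is None else gzip_output
            records = []
            for i in range(self.n_reads):
                records.append(f"@{self.sample_id}_{i}\n"
                               f"{seqs[i].tobytes().decode()}\n+\n"
                               f"{quals_to_string(quals[i])}\n")
            data = "".join(records)
            if use_gz:
                with gzip.open(path, "wt") as fh:
                    fh.write(data)
            else:
                path.write_text(data)


# ---------------------------------------------------------------------------
# simulate_panel
# ---------------------------------------------------------------------------

def simulate_panel(
    n_strains: int = 32,
    allele_length: int = 309,
    n_distinct_alleles: int | None = None,
    collision_spec: Mapping[str, Sequence[str]] | None = None,
    primer_fwd: str = DEFAULT_PRIMER_FWD,
    primer_rev: str = DEFAULT_PRIMER_REV,
    seed: int = 0,
    flank_length: int = 25,
    strain_ids: Sequence[str] | None = None,
) -> StrainPanel:
    """Generate a strain panel with a discriminating barcode window.

    ``collision_spec`` maps an allele label to the strains sharing that
    allele; strains not mentioned receive unique alleles.  If
    ``n_distinct_alleles`` is also given it must be consistent with the
    collision structure.  Deterministic under ``seed``.
    """
    if not primer_fwd or not primer_rev:
        raise ValueError("primers must be non-empty")
    rng = np.random.default_rng(seed)
    if strain_ids is None:
        strain_ids = [f"S{i + 1:02d}" for i in range(n_strains)]
    if len(strain_ids) != n_strains or len(set(strain_ids)) != n_strains:
        raise ValueError("strain_ids must be unique and match n_strains")

    collision_spec = dict(collision_spec or {})
    in_groups: list[str] = []
    for label, members in collision_spec.items():
        if len(members) < 2:
            raise ValueError(f"collision group {label!r} needs >= 2 strains")
        in_groups.extend(members)
    if len(set(in_groups)) != len(in_groups):
        raise ValueError("a strain appears in more than one collision group")
    unknown = set(in_groups) - set(strain_ids)
    if unknown:
        raise ValueError(f"collision_spec names unknown strains: {sorted(unknown)}")
    n_single = n_strains - len(in_groups)
    implied_distinct = n_single + len(collision_spec)
    if n_distinct_alleles is None:
        n_distinct_alleles = implied_distinct
    if not 1 <= n_distinct_alleles <= n_strains:
        raise ValueError("need 1 <= n_distinct_alleles <= n_strains")
    if collision_spec and n_distinct_alleles != implied_distinct:
        raise ValueError(
            f"collision_spec implies {implied_distinct} distinct alleles, "
            f"n_distinct_alleles={n_distinct_alleles} requested")
    if not collision_spec and n_distinct_alleles < n_strains:
        # fold surplus strains into collision groups on the first alleles
        singles = list(strain_ids[:n_distinct_alleles])
        extras = list(strain_ids[n_distinct_alleles:])
        groups: dict[str, list[str]] = {}
        for j, extra in enumerate(extras):
            anchor = singles[j % n_distinct_alleles]
            groups.setdefault(f"grp_{anchor}", [anchor]).append(extra)
        collision_spec = groups
        in_groups = [s for g in groups.values() for s in g]

    rc_rev = revcomp(primer_rev)

    def _fresh_allele(existing: set[str]) -> str:
        while True:
            allele = random_dna(rng, allele_length)
            marker = primer_fwd + allele + rc_rev
            if allele in existing:
                continue
            if marker.count(primer_fwd) != 1 or marker.count(rc_rev) != 1:
                continue
            return allele

    alleles: dict[str, str] = {}
    seen: set[str] = set()
    # collision groups first (deterministic order), then singletons
    for label in collision_spec:
        allele = _fresh_allele(seen)
        seen.add(allele)
        for sid in collision_spec[label]:
            alleles[sid] = allele
    for sid in strain_ids:
        if sid not in alleles:
            allele = _fresh_allele(seen)
            seen.add(allele)
            alleles[sid] = allele

    strains = []
    for sid in strain_ids:
        while True:
            left = random_dna(rng, flank_length)
            right = random_dna(rng, flank_length)
            marker = left + primer_fwd + alleles[sid] + rc_rev + right
            if marker.count(primer_fwd) == 1 and marker.count(rc_rev) == 1:
                break
        strains.append(Strain(sid, marker))
    return StrainPanel(strains, primer_fwd, primer_rev, allele_length)


# ---------------------------------------------------------------------------
# simulate_pangenome
# ---------------------------------------------------------------------------

MIN_GENE_LENGTH = 20   # below the aligner seed no presence call is possible


def simulate_pangenome(
    panel: StrainPanel,
    n_genes: int = 12,
    n_planted: int = 0,
    gene_length: int = 600,
    seed: int = 0,
    planted_carriers: Mapping[str, Sequence[str]] | None = None,
    shell_fraction: float = 0.0,
    n_genospecies: int = 1,
    genospecies_divergence: float = 0.06,
    within_divergence: float = 0.01,
    present_divergence: float = 0.02,
    decoys: Mapping[str, tuple[str, float]] | None = None,
    n_rh_groups: int = 2,
    backbone_length: int = 3000,
) -> PangenomeTruth:
    """Generate a presence/absence pangenome and per-strain genomes.

    Planted genes (``gene_001`` .. ``gene_{n_planted}``) are carried by a
    contiguous block of about half the strains in a randomised strain
    order, unless ``planted_carriers`` pins the carrier sets.  Null genes
    follow a U-shaped frequency spectrum (cloud genes in 1-3 strains,
    near-core genes missing from 1-3 strains); mid-frequency null genes
    are opt-in via ``shell_fraction`` because their random carrier sets
    can mimic true associations in small panels.

    Present genes are written into the carrier genome at
    ``1 - present_divergence`` identity; absent genes leave no homolog.
    ``decoys`` maps a gene to ``(strain, identity)`` to plant a diverged
    copy in a non-carrier (the truth matrix still records absence when
    the identity is at or below the 70% calling threshold).
    """
    if n_planted > n_genes:
        raise ValueError("n_planted must be <= n_genes")
    if gene_length < MIN_GENE_LENGTH:
        raise ValueError(
            f"gene_length < {MIN_GENE_LENGTH}: presence would be undetectable "
            "by the seed-and-extend aligner")
    rng = np.random.default_rng(seed)
    sids = panel.strain_ids
    n = len(sids)
    gene_ids = [f"gene_{i + 1:03d}" for i in range(n_genes)]
    planted = gene_ids[:n_planted]

    presence = pd.DataFrame(False, index=sids, columns=gene_ids)
    gene_seqs = {g: random_dna(rng, gene_length) for g in gene_ids}

    for g in planted:
        if planted_carriers and g in planted_carriers:
            carriers = list(planted_carriers[g])
        else:
            order = list(rng.permutation(sids))
            size = int(rng.integers(n // 2 - 2, n // 2 + 3)) if n >= 8 else max(1, n // 2)
            carriers = order[:size]
        presence.loc[carriers, g] = True
    for g in gene_ids[n_planted:]:
        u = rng.random()
        if u < shell_fraction:
            size = int(rng.integers(4, max(5, n - 3)))
        elif u < shell_fraction + (1 - shell_fraction) * 0.55:
            size = int(rng.integers(1, min(4, n + 1)))     # cloud
        else:
            size = n - int(rng.integers(1, 4))             # near-core
        carriers = list(rng.permutation(sids))[:size]
        presence.loc[carriers, g] = True

    # genospecies backbone structure
    root = random_dna(rng, backbone_length)
    gs_labels = [f"gs{i + 1}" for i in range(n_genospecies)]
    ancestors = {lab: mutate(root, genospecies_divergence, rng) if n_genospecies > 1
                 else root for lab in gs_labels}
    gs_truth = {sid: gs_labels[i % n_genospecies] for i, sid in enumerate(sids)}

    decoys = dict(decoys or {})
    genomes: dict[str, str] = {}
    for sid in sids:
        parts = [mutate(ancestors[gs_truth[sid]], within_divergence, rng)]
        for g in gene_ids:
            if presence.at[sid, g]:
                parts.append(random_dna(rng, 50))
                parts.append(mutate(gene_seqs[g], present_divergence, rng))
        for g, (decoy_strain, identity) in decoys.items():
            if decoy_strain == sid:
                if presence.at[sid, g]:
                    raise ValueError(f"decoy strain {sid} already carries {g}")
                parts.append(random_dna(rng, 50))
                parts.append(mutate(gene_seqs[g], 1.0 - identity, rng))
        strain = next(s for s in panel.strains if s.id == sid)
        parts.append(random_dna(rng, 50))
        parts.append(strain.marker_sequence)
        genomes[sid] = "".join(parts)

    # repABC cassette per synthetic replicon
    repa_refs = {f"Rh{i + 1:02d}": random_dna(rng, 400) for i in range(n_rh_groups)}
    repb = random_dna(rng, 300)
    repc = random_dna(rng, 300)
    replicons: dict[str, str] = {}
    rh_truth: dict[str, str] = {}
    rh_labels = sorted(repa_refs)
    for i, sid in enumerate(sids):
        lab = rh_labels[i % n_rh_groups]
        rh_truth[sid] = lab
        cassette = (random_dna(rng, 80)
                    + mutate(repa_refs[lab], 0.01, rng)
                    + random_dna(rng, 40)
                    + mutate(repb, 0.01, rng)
                    + random_dna(rng, 40)
                    + mutate(repc, 0.01, rng)
                    + random_dna(rng, 80))
        replicons[sid] = cassette

    return PangenomeTruth(
        presence=presence, gene_sequences=gene_seqs, genomes=genomes,
        planted_genes=planted, replicons=replicons, rh_truth=rh_truth,
        repa_references=repa_refs, repb_reference=repb, repc_reference=repc,
        genospecies_truth=gs_truth)


# ---------------------------------------------------------------------------
# simulate_host_propensities
# ---------------------------------------------------------------------------

def simulate_host_propensities(
    panel: StrainPanel,
    presence_truth: pd.DataFrame,
    planted_effects: Sequence[PlantedEffect],
    hosts: Sequence[str],
    n_replicates: int = 4,
    dirichlet_concentration: float = 100.0,
    depth: int = 14203,
    seed: int = 0,
) -> list[TruthMixture]:
    """Per-host base propensities with Dirichlet replicate noise.

    The base propensity of a strain on a host is the product of the
    effect sizes of the planted genes it carries (uniform when it
    carries none); replicate proportions are Dirichlet draws with
    concentration ``dirichlet_concentration * base``.  An infinite
    concentration returns the base proportions exactly.
    """
    sids = panel.strain_ids
    for eff in planted_effects:
        if eff.host_genotype not in hosts:
            raise ValueError(f"effect references unknown host {eff.host_genotype!r}")
        if eff.gene_id not in presence_truth.columns:
            raise ValueError(f"effect references unknown gene {eff.gene_id!r}")
    rng = np.random.default_rng(seed)
    mixtures: list[TruthMixture] = []
    for host in hosts:
        base = np.ones(len(sids))
        for eff in planted_effects:
            if eff.host_genotype != host:
                continue
            carrier = presence_truth[eff.gene_id].reindex(sids).to_numpy()
            base[carrier] *= eff.effect_size
        total = base.sum()
        if total <= 0:
            raise ValueError(f"zero total propensity for host {host!r}")
        base = base / total
        for rep in range(1, n_replicates + 1):
            if np.isinf(dirichlet_concentration):
                props = base.copy()
            else:
                props = np.zeros_like(base)
                pos = base > 0
                props[pos] = rng.dirichlet(dirichlet_concentration * base[pos])
            mixtures.append(TruthMixture(
                host_genotype=host, replicate=rep,
                proportions=dict(zip(sids, props)), depth=depth))
    return mixtures


# ---------------------------------------------------------------------------
# simulate_reads
# ---------------------------------------------------------------------------

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_TO_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate(_BASE_CODES):
    _CODE_TO_INDEX[_c] = _i


def _apply_errors(seq: np.ndarray, qual: np.ndarray,
                  rng: np.random.Generator) -> None:
    """Substitute bases in place at the probability implied by quality."""
    p = phred_error_prob(qual)
    hit = rng.random(seq.shape) < p
    if not hit.any():
        return
    idx = _CODE_TO_INDEX[seq[hit]]
    shift = rng.integers(1, 4, size=idx.size)
    seq[hit] = _BASE_CODES[(idx + shift) % 4]


def simulate_reads(
    panel: StrainPanel,
    mixture: TruthMixture,
    read_length: int = 250,
    error_rate: float = 0.0,
    tag: str = "",
    quality_model: QualityModel | None = None,
    seed: int = 0,
    minimum_overlap: int = 16,
    sample_id: str | None = None,
) -> ReadBatch:
    """Multinomial paired-end amplicon reads for one sample.

    The forward read covers ``tag + primer_fwd + allele prefix``; the
    reverse read is the reverse complement of the amplicon suffix.  The
    two overlap so that merging reconstructs the full tagged amplicon.
    Substitution errors are i.i.d. at ``error_rate`` with quality
    strings consistent with the two-state quality model.
    """
    if quality_model is None:
        quality_model = QualityModel()
    if read_length < len(panel.primer_fwd) + 1:
        raise ValueError("read_length must exceed primer length")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    amplicons = panel.amplicons
    amp_len = len(panel.primer_fwd) + panel.allele_length + len(panel.primer_rev)
    covered = (read_length - len(tag)) + read_length
    if amp_len > covered - minimum_overlap:
        raise ValueError("amplicon longer than 2*read_length - minimum_overlap: "
                         "unmergeable by construction")

    rng = np.random.default_rng(seed)
    sids = list(mixture.proportions)
    probs = np.array([mixture.proportions[s] for s in sids])
    counts = rng.multinomial(mixture.depth, probs)

    r1_rows, r2_rows, truth = [], [], []
    for sid, count in zip(sids, counts):
        if count == 0:
            continue
        amp = amplicons[sid]
        t1 = (tag + amp)[:read_length]
        t2 = revcomp(amp)[:read_length]
        r1_rows.append(np.tile(seq_to_array(t1), (count, 1)))
        r2_rows.append(np.tile(seq_to_array(t2), (count, 1)))
        truth.extend([sid] * count)
    r1 = np.vstack(r1_rows) if r1_rows else np.empty((0, read_length), dtype=np.uint8)
    r2 = np.vstack(r2_rows) if r2_rows else np.empty((0, read_length), dtype=np.uint8)
    truth_arr = np.array(truth, dtype=object)
    perm = rng.permutation(r1.shape[0])
    r1, r2, truth_arr = r1[perm].copy(), r2[perm].copy(), truth_arr[perm]

    low_frac = quality_model.low_fraction(error_rate)
    q1 = np.full(r1.shape, quality_model.q_high, dtype=np.int64)
    q2 = np.full(r2.shape, quality_model.q_high, dtype=np.int64)
    if error_rate > 0:
        if low_frac > 0:
            q1[rng.random(q1.shape) < low_frac] = quality_model.q_low
            q2[rng.random(q2.shape) < low_frac] = quality_model.q_low
            _apply_errors(r1, q1, rng)
            _apply_errors(r2, q2, rng)
        else:
            # error_rate below the high-quality error class: apply at the
            # requested rate directly (qualities then slightly pessimistic)
            for seq in (r1, r2):
                hit = rng.random(seq.shape) < error_rate
                idx = _CODE_TO_INDEX[seq[hit]]
                shift = rng.integers(1, 4, size=idx.size)
                seq[hit] = _BASE_CODES[(idx + shift) % 4]
    if sample_id is None:
        sample_id = f"{mixture.host_genotype}_rep{mixture.replicate}"
    return ReadBatch(sample_id, r1, q1, r2, q2, strain_truth=list(truth_arr))


# ---------------------------------------------------------------------------
# nod gene alignment with nested clade structure (for taxonomy tests)
# ---------------------------------------------------------------------------

def simulate_nod_alignment(
    panel: StrainPanel,
    n_types: int = 2,
    groups_per_type: int = 2,
    length: int = 2000,
    type_divergence: float = 0.15,
    group_divergence: float = 0.025,
    within_divergence: float = 0.005,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Equal-length concatenated nodulation-gene sequences with a nested
    two-level clade structure (types subdivided into groups), plus the
    truth labels."""
    rng = np.random.default_rng(seed)
    root = random_dna(rng, length)
    type_anc = [mutate(root, type_divergence, rng) for _ in range(n_types)]
    group_anc = {}
    for t in range(n_types):
        for g in range(groups_per_type):
            group_anc[(t, g)] = mutate(type_anc[t], group_divergence, rng)
    seqs: dict[str, str] = {}
    rows = []
    keys = sorted(group_anc)
    for i, sid in enumerate(panel.strain_ids):
        t, g = keys[i % len(keys)]
        seqs[sid] = mutate(group_anc[(t, g)], within_divergence, rng)
        rows.append({"strain_id": sid,
                     "nod_type": chr(ord("A") + t),
                     "nod_group": f"{chr(ord('A') + t)}{g + 1}"})
    truth = pd.DataFrame(rows).set_index("strain_id")
    return seqs, truth


# ---------------------------------------------------------------------------
# experiment orchestration and writers
# ---------------------------------------------------------------------------

DEFAULT_HOSTS = ("PK", "PI", "PJ", "LF", "LR", "LA", "FO", "FD", "FT")


@dataclass
class SyntheticExperiment:
    panel: StrainPanel
    pangenome: PangenomeTruth
    planted_effects: list[PlantedEffect]
    mixtures: list[TruthMixture]
    sample_sheet: pd.DataFrame           # sample_id, host_genotype, replicate, tag
    reads: dict[str, ReadBatch]
    parameters: dict

    def mixture_of(self, sample_id: str) -> TruthMixture:
        row = self.sample_sheet.loc[self.sample_sheet.sample_id == sample_id].iloc[0]
        for m in self.mixtures:
            if m.host_genotype == row.host_genotype and m.replicate == row.replicate:
                return m
        raise KeyError(sample_id)


def _distinct_tags(n: int, length: int, rng: np.random.Generator) -> list[str]:
    tags: list[str] = []
    seen = set()
    while len(tags) < n:
        t = random_dna(rng, length)
        if t not in seen:
            seen.add(t)
            tags.append(t)
    return tags


def simulate_experiment(
    hosts: Sequence[str] = DEFAULT_HOSTS,
    n_replicates: int = 4,
    n_strains: int = 32,
    n_collisions: int = 1,
    depth: int = 14203,
    error_rate: float = 0.005,
    read_length: int = 250,
    n_genes: int = 12,
    n_planted: int = 4,
    effect_size: float = 10.0,
    dirichlet_concentration: float = 100.0,
    tag_length: int = DEFAULT_TAG_LENGTH,
    seed: int = 0,
) -> SyntheticExperiment:
    """Full stated-world experiment: panel, pangenome with planted
    host-specific effects, replicate mixtures, and error-bearing reads."""
    rng = np.random.default_rng(seed)
    collision_spec = None
    if n_collisions:
        sids = [f"S{i + 1:02d}" for i in range(n_strains)]
        collision_spec = {f"col{j + 1}": [sids[2 * j], sids[2 * j + 1]]
                          for j in range(n_collisions)}
    panel = simulate_panel(n_strains=n_strains, collision_spec=collision_spec,
                           seed=int(rng.integers(2**31)))
    pangenome = simulate_pangenome(panel, n_genes=n_genes, n_planted=n_planted,
                                   seed=int(rng.integers(2**31)))
    effects = [PlantedEffect(g, hosts[i % len(hosts)], effect_size)
               for i, g in enumerate(pangenome.planted_genes)]
    mixtures = simulate_host_propensities(
        panel, pangenome.presence, effects, hosts, n_replicates=n_replicates,
        dirichlet_concentration=dirichlet_concentration, depth=depth,
        seed=int(rng.integers(2**31)))
    tags = _distinct_tags(len(mixtures), tag_length, rng)
    reads: dict[str, ReadBatch] = {}
    sheet_rows = []
    for mix, tag in zip(mixtures, tags):
        sample_id = f"{mix.host_genotype}_r{mix.replicate}"
        reads[sample_id] = simulate_reads(
            panel, mix, read_length=read_length, error_rate=error_rate,
            tag=tag, seed=int(rng.integers(2**31)), sample_id=sample_id)
        sheet_rows.append({"sample_id": sample_id,
                           "host_genotype": mix.host_genotype,
                           "replicate": mix.replicate, "tag": tag})
    sheet = pd.DataFrame(sheet_rows)
    params = {"hosts": list(hosts), "n_replicates": n_replicates,
              "n_strains": n_strains, "n_collisions": n_collisions,
              "depth": depth, "error_rate": error_rate,
              "read_length": read_length, "n_genes": n_genes,
              "n_planted": n_planted, "effect_size": effect_size,
              "dirichlet_concentration": dirichlet_concentration,
              "tag_length": tag_length, "seed": seed}
    return SyntheticExperiment(panel, pangenome, effects, mixtures, sheet,
                               reads, params)


def write_experiment(exp: SyntheticExperiment, outdir) -> None:
    """Write FASTQ pairs, sample sheet, panel FASTA, truth tables and a
    JSON manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample_id, batch in exp.reads.items():
        batch.to_fastq(outdir / f"{sample_id}_R1.fastq",
                       outdir / f"{sample_id}_R2.fastq")
    exp.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    with open(outdir / "panel.fasta", "w") as fh:
        for s in exp.panel.strains:
            fh.write(f">{s.id}\n{s.marker_sequence}\n")
    # truth barcode reference (inter-primer windows)
    from .barcode import reference_from_panel
    reference_from_panel(exp.panel).write_fasta(outdir / "reference.fasta")
    exp.pangenome.presence.astype(int).to_csv(outdir / "presence_truth.tsv", sep="\t")
    prop_rows = []
    for m in exp.mixtures:
        for sid, p in m.proportions.items():
            prop_rows.append({"host_genotype": m.host_genotype,
                              "replicate": m.replicate, "strain_id": sid,
                              "proportion": p})
    pd.DataFrame(prop_rows).to_csv(outdir / "proportions_truth.tsv",
                                   sep="\t", index=False)
    pd.DataFrame([vars(e) for e in exp.planted_effects]).to_csv(
        outdir / "planted_effects.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(json.dumps(exp.parameters, indent=2))
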