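"""Barcode window design and allele reference construction.

Given a pre-aligned marker-gene alignment across a strain collection,
scan fixed-length windows flanked by conserved primer sites, pick the
most discriminating window, build the allele reference (allele -> member
strains, with collision groups where several strains share an allele),
and select a core collection with one representative strain per allele.

Coordinates are 0-based, half-open.  Window allele strings are
gap-stripped before comparison; degenerate IUPAC characters compare by
exact character, matching the strict string identity used downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .synth import StrainPanel


@dataclass(frozen=True)
class WindowReport:
    """Discrimination report for one candidate barcode window."""

    start: int            # 0-based inclusive offset in the alignment
    length: int
    n_alleles: int
    primer_ok: bool


@dataclass
class BarcodeReference:
    """Allele reference: pairwise-distinct allele sequences, the strains
    carrying each allele, and the collision groups (alleles shared by two
    or more strains, indistinguishable by the barcode)."""

    alleles: dict[str, str]               # allele_id -> sequence
    membership: dict[str, list[str]]      # allele_id -> sorted strain ids

    def __post_init__(self) -> None:
        seqs = list(self.alleles.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("allele sequences must be pairwise distinct")
        all_strains = [s for m in self.membership.values() for s in m]
        if len(set(all_strains)) != len(all_strains):
            raise ValueError("a strain appears under more than one allele")

    @property
    def collision_groups(self) -> dict[str, list[str]]:
        return {a: m for a, m in self.membership.items() if len(m) >= 2}

    @property
    def strain_ids(self) -> list[str]:
        return sorted(s for m in self.membership.values() for s in m)

    def row_labels(self) -> dict[str, str]:
        """allele_id -> count-table row label (member ids joined by '+')."""
        return {a: "+".join(m) for a, m in self.membership.items()}

    def sequence_to_label(self) -> dict[str, str]:
        labels = self.row_labels()
        return {seq: labels[a] for a, seq in self.alleles.items()}

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for a in sorted(self.alleles):
                members = ",".join(self.membership[a])
                fh.write(f">{a} members={members}\n{self.alleles[a]}\n")


# ---------------------------------------------------------------------------
# window scanning and selection
# ---------------------------------------------------------------------------

def _check_aligned(aligned: Mapping[str, str]) -> int:
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise ValueError(
            "sequences have unequal lengths: input must be a pre-computed "
            "multiple alignment (alignment itself is out of scope)")
    return lengths.pop()


def _consensus_mismatches(columns: list[str]) -> list[int]:
    """Per-sequence mismatch counts against the column-consensus of a
    block of aligned columns (ties broken by lexicographic order)."""
    n_seq = len(columns[0])
    mismatches = [0] * n_seq
    for col in columns:
        counts = Counter(col)
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0][0])))
        # deterministic tie-break: highest count, then smallest character
        top = best[1]
        consensus = min(c for c, k in counts.items() if k == top)
        for i, c in enumerate(col):
            if c != consensus:
                mismatches[i] += 1
    return mismatches


def scan_windows(
    aligned_markers: Mapping[str, str],
    window_length: int,
    primer_length: int,
    max_primer_mismatch: int = 1,
) -> list[WindowReport]:
    """One report per admissible window start.

    ``n_alleles`` counts distinct gap-stripped window strings;
    ``primer_ok`` is true iff in both flanking ``primer_length`` blocks
    every strain is within ``max_primer_mismatch`` of the column
    consensus.
    """
    aln_len = _check_aligned(aligned_markers)
    if window_length + 2 * primer_length > aln_len:
        raise ValueError("window plus primers exceed alignment length")
    ids = list(aligned_markers)
    rows = [aligned_markers[i] for i in ids]
    reports = []
    for start in range(primer_length, aln_len - window_length - primer_length + 1):
        window_strings = {row[start:start + window_length].replace("-", "")
                          for row in rows}
        left_cols = [
            "".join(row[j] for row in rows)
            for j in range(start - primer_length, start)]
        right_cols = [
            "".join(row[j] for row in rows)
            for j in range(start + window_length, start + window_length + primer_length)]
        ok = (max(_consensus_mismatches(left_cols)) <= max_primer_mismatch
              and max(_consensus_mismatches(right_cols)) <= max_primer_mismatch)
        reports.append(WindowReport(start=start, length=window_length,
                                    n_alleles=len(window_strings), primer_ok=ok))
    return reports


def select_barcode(reports: Sequence[WindowReport],
                   tie_break: str = "leftmost") -> WindowReport:
    """The primer-conserved window maximising allele count; ties go to
    the leftmost start."""
    admissible = [r for r in reports if r.primer_ok]
    if not admissible:
        raise ValueError("no conserved primer site: no admissible window")
    if tie_break != "leftmost":
        raise ValueError(f"unknown tie_break {tie_break!r}")
    best = max(admissible, key=lambda r: (r.n_alleles, -r.start))
    return best


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def build_reference(windows: Mapping[str, str]) -> BarcodeReference:
    """Group strains by their (gap-stripped) barcode window sequence.

    Allele ids are ``a`` + the lexicographically first member strain, so
    labels are stable under input reordering.
    """
    groups: dict[str, list[str]] = {}
    for sid, seq in windows.items():
        groups.setdefault(seq.replace("-", ""), []).append(sid)
    alleles: dict[str, str] = {}
    membership: dict[str, list[str]] = {}
    for seq, members in groups.items():
        members = sorted(members)
        allele_id = f"a_{members[0]}"
        alleles[allele_id] = seq
        membership[allele_id] = members
    return BarcodeReference(alleles=alleles, membership=membership)


def reference_from_alignment(aligned_markers: Mapping[str, str],
                             window: WindowReport) -> BarcodeReference:
    _check_aligned(aligned_markers)
    return build_reference({sid: seq[window.start:window.start + window.length]
                            for sid, seq in aligned_markers.items()})


def reference_from_panel(panel: StrainPanel) -> BarcodeReference:
    """Reference straight from a synthetic panel's inter-primer windows."""
    return build_reference(panel.alleles)


# ---------------------------------------------------------------------------
# strain metadata and core-collection selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrainMetadata:
    """Classification metadata of one strain (genospecies, nodulation
    type/group, nodX carriage, host of isolation, geographic origin)."""

    strain_id: str
    genospecies: str
    nod_type: str
    nod_group: str
    nodX: bool = False
    host_of_isolation: str = ""
    origin: str = ""

    def __post_init__(self) -> None:
        if self.nod_group and self.nod_type and \
                not self.nod_group.startswith(self.nod_type):
            raise ValueError(
                f"nod_group {self.nod_group!r} does not refine nod_type "
                f"{self.nod_type!r}")


def select_core_collection(
    reference: BarcodeReference,
    metadata: Mapping[str, StrainMetadata],
    target_size: int | None = None,
) -> list[str]:
    """Pick exactly one strain per allele, greedily maximising coverage of
    genospecies/Nod-group combinations, then hosts of isolation, then
    origins, then nodX balance.  Deterministic given input order."""
    n_alleles = len(reference.alleles)
    if target_size is None:
        target_size = n_alleles
    if target_size > n_alleles:
        raise ValueError("target_size exceeds the number of distinct alleles: "
                         "unique barcodes are impossible")
    covered_combo: set[tuple[str, str]] = set()
    covered_host: set[str] = set()
    covered_origin: set[str] = set()
    n_nodx = 0
    selection: list[str] = []
    # smaller-membership alleles first so constrained choices come early;
    # allele id breaks ties deterministically
    order = sorted(reference.membership,
                   key=lambda a: (len(reference.membership[a]), a))
    for allele_id in order:
        members = reference.membership[allele_id]

        def gain(sid: str) -> tuple:
            md = metadata[sid]
            combo = (md.genospecies, md.nod_group)
            balance = -abs((n_nodx + int(md.nodX)) - (len(selection) + 1) / 2)
            return (combo not in covered_combo,
                    md.host_of_isolation not in covered_host,
                    md.origin not in covered_origin,
                    balance)

        best_gain = max(gain(sid) for sid in members)
        chosen = min(sid for sid in members if gain(sid) == best_gain)
        md = metadata[chosen]
        covered_combo.add((md.genospecies, md.nod_group))
        covered_host.add(md.host_of_isolation)
        covered_origin.add(md.origin)
        n_nodx += int(md.nodX)
        selection.append(chosen)
    if target_size < len(selection):
        # keep the prefix of the greedy order (most constrained alleles kept)
        selection = selection[:target_size]
    return sorted(selection)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_aligned_fasta(path) -> dict[str, str]:
    aligned = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    _check_aligned(aligned)
    return aligned


def metadata_from_table(table: pd.DataFrame) -> dict[str, StrainMetadata]:
    """Build :class:`StrainMetadata` records from a table with columns
    strain_id, genospecies, nod_type, nod_group[, nodX, host_of_isolation,
    origin]."""
    out = {}
    for _, row in table.iterrows():
        out[row["strain_id"]] = StrainMetadata(
            strain_id=row["strain_id"],
            genospecies=row["genospecies"],
            nod_type=row["nod_type"],
            nod_group=row["nod_group"],
            nodX=bool(row.get("nodX", False)),
            host_of_isolation=str(row.get("host_of_isolation", "")),
            origin=str(row.get("origin", "")))
    return out


def window_reports_to_table(reports: Sequence[WindowReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])
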