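"""Readers for the three input formats and per-kinase dataset assembly.

The tool consumes three plain-text inputs:

* substrate protein sequences (FASTA),
* a phosphosite annotation table (TSV: ``substrate_id``, 1-based
  ``position``, ``residue``, semicolon-separated ``kinases``),
* a protein-protein interaction edge list (STRING-like TSV with an
  optional 0-1000 confidence score).

For a given kinase the labeled dataset takes every annotated site as a
sample: sites annotated to that kinase are positives, all remaining
sites are negatives.  Kinases with fewer than ``min_positives``
(default 25) annotated sites are rejected, which keeps per-kinase
models trained on a reasonable number of examples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

SITE_TABLE_COLUMNS = ("substrate_id", "position", "residue", "kinases")


class InputError(ValueError):
    """A malformed or inconsistent input file."""


class DatasetRejected(ValueError):
    """A kinase failed the minimum-positive-count filter."""


@dataclass
class ProteinSequenceSet:
    """Substrate sequences keyed by identifier (upper-cased on ingest)."""

    entries: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __getitem__(self, key: str) -> str:
        return self.entries[key]


@dataclass(frozen=True)
class SiteRecord:
    """One annotated phosphosite.

    ``position`` is 1-based; ``kinases`` holds every kinase annotating
    the site (possibly empty for sites with no known modifier).
    """

    substrate_id: str
    position: int
    residue: str
    kinases: frozenset[str] = frozenset()


@dataclass
class PPINetwork:
    """Undirected interaction network with optional STRING-style scores.

    ``partner_universe`` is the lexicographically sorted list of every
    identifier that occurs in an edge; functional feature vectors are
    indexed against this order.
    """

    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    partner_universe: list[str] = field(default_factory=list)
    _neighbors: dict[str, dict[str, float]] = field(default_factory=dict, repr=False)

    def neighbors(self, protein: str) -> dict[str, float]:
        """Interaction partners of ``protein`` with their scores."""
        return self._neighbors.get(protein, {})

    @classmethod
    def from_edges(cls, scored_edges: dict[tuple[str, str], float]) -> "PPINetwork":
        neighbors: dict[str, dict[str, float]] = {}
        for (a, b), score in scored_edges.items():
            neighbors.setdefault(a, {})[b] = score
            neighbors.setdefault(b, {})[a] = score
        universe = sorted(neighbors)
        return cls(edges=scored_edges, partner_universe=universe, _neighbors=neighbors)


@dataclass
class KinaseDataset:
    """Labeled samples for one kinase: label +1 iff the kinase annotates the site."""

    kinase: str
    samples: list[SiteRecord]
    labels: np.ndarray  # values in {+1, -1}, aligned with samples

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.labels == -1))


def read_fasta(path: str | Path) -> ProteinSequenceSet:
    """Read a FASTA file into a :class:`ProteinSequenceSet`.

    The identifier is the header token before the first whitespace.
    Sequences are upper-cased.  Duplicate identifiers are an error.
    """
    path = Path(path)
    entries: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise InputError(f"malformed FASTA in {path}: {exc}") from exc
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise InputError(f"empty sequence for record {rec.id!r} in {path}")
        if rec.id in entries:
            raise InputError(f"duplicate identifier {rec.id!r} in {path}")
        entries[rec.id] = seq
    if not entries:
        logger.warning("FASTA file %s contained no records", path)
    return ProteinSequenceSet(entries=entries)


def read_site_table(path: str | Path) -> list[SiteRecord]:
    """Read the phosphosite TSV; duplicate (substrate, position) rows are
    merged by union of their kinase sets."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SITE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"site table {path} lacks columns {missing}")
    merged: dict[tuple[str, int], dict] = {}
    order: list[tuple[str, int]] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        line_no = idx + 2  # 1-based, after the header line
        try:
            position = int(row.position)
        except ValueError as exc:
            raise InputError(
                f"{path} line {line_no}: non-integer position {row.position!r}"
            ) from exc
        kinases = frozenset(k.strip() for k in row.kinases.split(";") if k.strip())
        key = (row.substrate_id, position)
        if key in merged:
            prev = merged[key]
            if prev["residue"] != row.residue.upper():
                raise InputError(
                    f"{path} line {line_no}: residue conflict at {key}"
                )
            prev["kinases"] |= kinases
        else:
            merged[key] = {"residue": row.residue.upper(), "kinases": set(kinases)}
            order.append(key)
    return [
        SiteRecord(
            substrate_id=sub,
            position=pos,
            residue=merged[(sub, pos)]["residue"],
            kinases=frozenset(merged[(sub, pos)]["kinases"]),
        )
        for sub, pos in order
    ]


def write_site_table(path: str | Path, sites: list[SiteRecord]) -> Path:
    """Write sites back to the TSV dialect read by :func:`read_site_table`."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(SITE_TABLE_COLUMNS) + "\n")
        for site in sites:
            kin = ";".join(sorted(site.kinases))
            fh.write(f"{site.substrate_id}\t{site.position}\t{site.residue}\t{kin}\n")
    return path


def _looks_like_header(fields: list[str]) -> bool:
    first = fields[0].lower()
    if first.startswith("#") or first.startswith("protein") or first.startswith("node"):
        return True
    if len(fields) >= 3:
        try:
            float(fields[2])
        except ValueError:
            return True
    return False


def read_ppi(path: str | Path, score_cutoff: float = 0.0) -> PPINetwork:
    """Read a STRING-like edge list TSV.

    Edges with score below ``score_cutoff`` are dropped (the default 0
    keeps everything).  Self-loops are removed, (A,B)/(B,A) duplicates
    are collapsed to one undirected edge keeping the maximal score, and
    edges without a score column get score 1000 (full confidence).
    """
    path = Path(path)
    edges: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        logger.warning("PPI file %s is empty", path)
        return PPINetwork.from_edges({})
    start = 1 if _looks_like_header(lines[0].split("\t")) else 0
    for line_no, line in enumerate(lines[start:], start=start + 1):
        fields = line.split("\t")
        if len(fields) < 2:
            raise InputError(f"{path} line {line_no}: fewer than 2 columns")
        a, b = fields[0].strip(), fields[1].strip()
        if a == b:
            continue  # self-loop
        score = 1000.0
        if len(fields) >= 3 and fields[2].strip():
            try:
                score = float(fields[2])
            except ValueError as exc:
                raise InputError(
                    f"{path} line {line_no}: non-numeric score {fields[2]!r}"
                ) from exc
        if score < score_cutoff:
            continue
        key = (a, b) if a < b else (b, a)
        edges[key] = max(score, edges.get(key, float("-inf")))
    return PPINetwork.from_edges(edges)


def validate_sites(sites: list[SiteRecord], sequences: ProteinSequenceSet) -> None:
    """Check positions are in range and residues match the sequences."""
    problems = []
    for site in sites:
        if site.substrate_id not in sequences:
            continue
        seq = sequences[site.substrate_id]
        if not 1 <= site.position <= len(seq):
            problems.append(f"{site.substrate_id}:{site.position} out of range")
        elif seq[site.position - 1] != site.residue:
            problems.append(
                f"{site.substrate_id}:{site.position} residue "
                f"{site.residue} != sequence {seq[site.position - 1]}"
            )
    if problems:
        raise InputError("site/sequence mismatches: " + "; ".join(problems))


def build_kinase_dataset(
    sites: list[SiteRecord], kinase: str, min_positives: int = 25
) -> KinaseDataset:
    """Assemble the labeled dataset for one kinase.

    Raises :class:`DatasetRejected` when the kinase annotates fewer than
    ``min_positives`` sites (or none at all).
    """
    if not sites:
        raise InputError("site list is empty")
    kinase = kinase.strip()
    labels = np.array(
        [1 if kinase in site.kinases else -1 for site in sites], dtype=np.int64
    )
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0:
        raise DatasetRejected(f"kinase {kinase!r} has zero positive sites")
    if n_pos < min_positives:
        raise DatasetRejected(
            f"kinase {kinase!r} has {n_pos} positive sites, "
            f"below the minimum of {min_positives}"
        )
    return KinaseDataset(kinase=kinase, samples=list(sites), labels=labels)


def available_kinases(sites: list[SiteRecord]) -> dict[str, int]:
    """Map every annotating kinase to its positive-site count."""
    counts: dict[str, int] = {}
    for site in sites:
        for kin in site.kinases:
            counts[kin] = counts.get(kin, 0) + 1
    return dict(sorted(counts.items()))
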