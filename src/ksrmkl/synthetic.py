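"""Synthetic benchmark generator with the statistical structure the
predictor exploits.

The generator plants two signals:

* **sequence signal** — each kinase has a consensus motif (a short
  string over the amino-acid alphabet with ``.`` wildcards, centered on
  the phosphoacceptor).  Positive-site windows match each determined
  motif position with probability ``motif_fidelity``; everything else is
  i.i.d. uniform over the 20 standard residues.
* **functional signal** — each kinase owns a set of hub partners in the
  PPI network.  Substrates in that kinase's cohort link to each hub with
  probability ``p_in``; every substrate links to any partner with the
  background probability ``p_out``.  Substrates of the same kinase thus
  preferentially share interaction partners.

Substrates are assigned round-robin to the kinase cohorts plus one
background cohort.  On a cohort substrate each site is annotated to the
cohort kinase with probability ``fraction_positive``; all remaining
sites are unannotated negatives.  Because every real phosphosite is
written by *some* kinase, negative sites are not plain random windows:
each one carries a consensus motif drawn from a pool of background
kinases (``background_motifs``), planted with the same per-position
fidelity mechanism.  Background consensi partially overlap the modeled
kinases' motifs, which keeps sequence-only separation good but
imperfect — the regime in which the functional view has something to
add.  The output is fully reproducible from the seed and round-trips
through the data_io readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import PPINetwork, ProteinSequenceSet, SiteRecord, write_site_table

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ACCEPTORS = "STY"
WILDCARD = "."


@dataclass(frozen=True)
class KinaseSpec:
    """A kinase with its consensus motif.

    The motif is centered on the site: with a length-7 motif, character
    0 sits at position -3 and character 6 at +3 relative to the
    phosphoacceptor.  The center character must be a concrete residue
    (the acceptor, e.g. S or T); ``.`` marks unconstrained positions.
    """

    name: str
    motif: str
    fidelity: float = 0.95

    def __post_init__(self):
        if len(self.motif) % 2 != 1:
            raise ValueError("motif length must be odd (centered on the site)")
        center = self.motif[len(self.motif) // 2]
        if center == WILDCARD:
            raise ValueError("motif center must be a concrete acceptor residue")
        if not 0.0 <= self.fidelity <= 1.0:
            raise ValueError("fidelity must lie in [0, 1]")


DEFAULT_KINASES = (
    KinaseSpec("KIN_A", "RR.S...", fidelity=0.9),  # basophilic, PKA-like R-R-x-S
    KinaseSpec("KIN_B", "...S.EE", fidelity=0.9),  # acidophilic, CK2-like S-x-E-E
)

# Consensi of the unmodeled kinases that wrote the negative sites; they
# deliberately share determinants with the modeled kinases (basic
# residues near the acceptor, acidic residues downstream) the way real
# kinase families do, so sequence alone separates well but not perfectly.
DEFAULT_BACKGROUND_MOTIFS = (
    "RR.T...",  # basophilic threonine cousin: both basic residues
    ".R.S...",  # basophilic cousin: R at -2 only
    "R..S...",  # basophilic cousin: R at -3 only
    "...S.E.",  # acidophilic cousin: E at +2 only
    "...T.EE",  # acidophilic threonine cousin
)


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_substrates: int = 42
    sites_per_substrate: int = 3
    kinases: tuple[KinaseSpec, ...] = DEFAULT_KINASES
    ppi_universe_size: int = 120
    hubs_per_kinase: int = 14
    p_in: float = 0.8
    p_out: float = 0.05
    fraction_positive: float = 0.95
    flank: int = 7
    background_motifs: tuple[str, ...] = DEFAULT_BACKGROUND_MOTIFS
    background_fidelity: float = 0.9
    # With cohort_labels, positives concentrate on the kinase-cohort
    # substrates (the realistic case: a kinase phosphorylates its
    # substrates at many sites).  Without it, annotations are scattered
    # uniformly over sites of all substrates at the same expected rate,
    # decoupling labels from substrate identity — required for a clean
    # no-signal control because the functional view is substrate-level.
    cohort_labels: bool = True

    def __post_init__(self):
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if not 0.0 <= self.fraction_positive <= 1.0:
            raise ValueError("fraction_positive must lie in [0, 1]")
        window = 2 * self.flank + 1
        for kin in self.kinases:
            if len(kin.motif) > window:
                raise ValueError(
                    f"motif of {kin.name} longer than the {window}-residue window"
                )
        for motif in self.background_motifs:
            if len(motif) > window:
                raise ValueError(f"background motif {motif!r} longer than the window")
        if self.ppi_universe_size < self.hubs_per_kinase * len(self.kinases):
            raise ValueError("ppi_universe_size smaller than the hub sets")


@dataclass
class SyntheticDataset:
    sequences: ProteinSequenceSet
    sites: list[SiteRecord]
    ppi: PPINetwork
    truth: pd.DataFrame  # substrate_id, position, kinase, label
    config: SyntheticConfig = field(repr=False, default=None)


def _plant_motif(
    seq: list[str], pos: int, motif: str, fidelity: float, rng: np.random.Generator
) -> None:
    """Overwrite the window around 1-based ``pos`` with the motif; the
    center is planted deterministically, every other determined position
    with probability ``fidelity``."""
    center = len(motif) // 2
    for m, ch in enumerate(motif):
        if ch == WILDCARD:
            continue
        if m == center or rng.random() < fidelity:
            seq[pos - 1 + m - center] = ch


def _site_positions(config: SyntheticConfig) -> list[int]:
    """1-based, non-overlapping window centers along each substrate."""
    step = 2 * config.flank + 2
    return [config.flank + 1 + j * step for j in range(config.sites_per_substrate)]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate sequences, annotated sites, a PPI network and the truth
    table; byte-identical outputs for identical configs."""
    rng = np.random.default_rng(config.seed)
    kinases = config.kinases
    n_cohorts = len(kinases) + 1  # last cohort: background, no kinase
    positions = _site_positions(config)
    seq_len = positions[-1] + config.flank
    aa = np.array(list(AMINO_ACIDS))

    entries: dict[str, str] = {}
    sites: list[SiteRecord] = []
    truth_rows = []
    cohort_of: dict[str, int] = {}
    for i in range(config.n_substrates):
        sub_id = f"SUB_{i:04d}"
        cohort = i % n_cohorts
        cohort_of[sub_id] = cohort
        seq = list(rng.choice(aa, size=seq_len))
        kin = kinases[cohort] if cohort < len(kinases) else None
        for pos in positions:
            if config.cohort_labels:
                site_kin = kin if rng.random() < config.fraction_positive else None
            else:
                # uniform scatter at the same expected per-kinase rate
                u = rng.random()
                rate = config.fraction_positive / n_cohorts
                j = int(u / rate) if u < rate * len(kinases) else len(kinases)
                site_kin = kinases[j] if j < len(kinases) else None
            positive = site_kin is not None
            if positive:
                _plant_motif(seq, pos, site_kin.motif, site_kin.fidelity, rng)
            elif config.background_motifs:
                decoy = config.background_motifs[
                    int(rng.integers(len(config.background_motifs)))
                ]
                _plant_motif(seq, pos, decoy, config.background_fidelity, rng)
            else:
                seq[pos - 1] = rng.choice(list(ACCEPTORS))
            residue = seq[pos - 1]
            annot = frozenset({site_kin.name}) if positive else frozenset()
            sites.append(SiteRecord(sub_id, pos, residue, annot))
            truth_rows.append(
                {
                    "substrate_id": sub_id,
                    "position": pos,
                    "kinase": site_kin.name if positive else "",
                    "label": 1 if positive else -1,
                }
            )
        entries[sub_id] = "".join(seq)

    sequences = ProteinSequenceSet(entries=entries)

    # PPI: kinase hub partners + background partners to fill the universe
    partners: list[str] = []
    hubs_of: dict[str, list[str]] = {}
    for kin in kinases:
        hubs = [f"HUB_{kin.name}_{h:02d}" for h in range(config.hubs_per_kinase)]
        hubs_of[kin.name] = hubs
        partners.extend(hubs)
    n_background = config.ppi_universe_size - len(partners)
    partners.extend(f"PAN_{j:04d}" for j in range(n_background))

    edges: dict[tuple[str, str], float] = {}
    for i in range(config.n_substrates):
        sub_id = f"SUB_{i:04d}"
        cohort = cohort_of[sub_id]
        hub_set = set(hubs_of[kinases[cohort].name]) if cohort < len(kinases) else set()
        for partner in partners:
            p = config.p_in if partner in hub_set else config.p_out
            if rng.random() < p:
                key = (sub_id, partner) if sub_id < partner else (partner, sub_id)
                edges[key] = float(rng.integers(200, 1000))
    ppi = PPINetwork.from_edges(edges)

    truth = pd.DataFrame(truth_rows, columns=["substrate_id", "position", "kinase", "label"])
    return SyntheticDataset(
        sequences=sequences, sites=sites, ppi=ppi, truth=truth, config=config
    )


def null_config(seed: int = 0) -> SyntheticConfig:
    """Matched no-signal control: every site is a bare S-centered window
    (no flank determinants for positives or negatives) and cohort
    substrates link to hubs at the background rate, so labels are
    independent of both feature views."""
    flat = (
        KinaseSpec("KIN_A", "...S...", fidelity=0.05),
        KinaseSpec("KIN_B", "...S...", fidelity=0.05),
    )
    return SyntheticConfig(
        seed=seed,
        kinases=flat,
        background_motifs=("...S...",),
        background_fidelity=0.05,
        p_in=0.05,
        p_out=0.05,
        cohort_labels=False,
    )


def write_fixture(outdir: str | Path, data: SyntheticDataset) -> dict[str, Path]:
    """Write FASTA + site TSV + PPI TSV + truth TSV in the data_io dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "sequences.fasta",
        "sites": outdir / "sites.tsv",
        "ppi": outdir / "ppi.tsv",
        "truth": outdir / "truth.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        for sub_id, seq in data.sequences.entries.items():
            fh.write(f">{sub_id}\n{seq}\n")
    write_site_table(paths["sites"], data.sites)
    with open(paths["ppi"], "w") as fh:
        fh.write("protein_a\tprotein_b\tscore\n")
        for (a, b), score in sorted(data.ppi.edges.items()):
            fh.write(f"{a}\t{b}\t{score:.0f}\n")
    data.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
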