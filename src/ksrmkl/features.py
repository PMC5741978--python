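"""Feature views: binary-encoded sequence windows and PPI indicator vectors.

Each phosphosite yields two feature vectors kept as separate views:

* **sequence view** — the local sequence window of ``flank`` residues on
  either side of the site (default 7, so a 15-mer) with each position
  one-hot encoded over a 21-symbol alphabet (20 standard amino acids
  plus one catch-all), giving a 15 x 21 = 315-dimensional binary vector;
* **functional view** — a per-substrate vector over the PPI partner
  universe, 1 where the substrate interacts with the partner (binary
  mode) or score/1000 (score mode).  Every site of a substrate shares
  the substrate's functional vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import InputError, KinaseDataset, PPINetwork, ProteinSequenceSet

# 20 standard amino acids in alphabetical order, then the catch-all 'X'
# used both for terminal padding and for non-standard residues.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
CATCH_ALL = "X"
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
N_SYMBOLS = len(ALPHABET)

DEFAULT_FLANK = 7


@dataclass
class FeatureViews:
    """Aligned per-sample feature matrices for the two views."""

    seq: np.ndarray | None  # samples x (window_length * 21), binary
    func: np.ndarray | None  # samples x |partner_universe|
    feature_counts: dict[str, int]

    def matrices(self, views: tuple[str, ...] | None = None) -> dict[str, np.ndarray]:
        """Selected view matrices in a fixed (seq, func) order."""
        available = {}
        if self.seq is not None:
            available["seq"] = self.seq
        if self.func is not None:
            available["func"] = self.func
        if views is None:
            return available
        out = {}
        for name in views:
            if name not in available:
                raise ValueError(f"view {name!r} not available (have {list(available)})")
            out[name] = available[name]
        return out


def extract_window(sequence: str, position: int, flank: int = DEFAULT_FLANK) -> str:
    """Local sequence window of length ``2*flank + 1`` centered on a
    1-based ``position``; positions beyond the termini are padded with
    the catch-all symbol."""
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    idx = position - 1
    chars = []
    for offset in range(-flank, flank + 1):
        j = idx + offset
        chars.append(sequence[j] if 0 <= j < len(sequence) else CATCH_ALL)
    return "".join(chars)


def encode_window(window: str) -> np.ndarray:
    """One-hot encode a window over the 21-symbol alphabet.

    Returns a binary vector of length ``len(window) * 21`` with exactly
    ``len(window)`` ones; unknown characters map to the catch-all slot.
    """
    vec = np.zeros(len(window) * N_SYMBOLS, dtype=np.float64)
    for i, ch in enumerate(window):
        vec[i * N_SYMBOLS + _INDEX.get(ch.upper(), _INDEX[CATCH_ALL])] = 1.0
    return vec


def encode_function(
    substrate_id: str, ppi: PPINetwork, mode: str = "binary"
) -> np.ndarray:
    """Functional vector of a substrate over the PPI partner universe.

    Binary mode sets 1 for every interaction partner; score mode uses
    score/1000 (the STRING confidence convention).  Substrates absent
    from the network get the all-zero vector.
    """
    if not ppi.partner_universe:
        raise ValueError("PPI network has an empty partner universe")
    if mode not in ("binary", "score"):
        raise ValueError(f"unknown functional mode {mode!r}")
    vec = np.zeros(len(ppi.partner_universe), dtype=np.float64)
    neighbors = ppi.neighbors(substrate_id)
    if neighbors:
        index = {p: i for i, p in enumerate(ppi.partner_universe)}
        for partner, score in neighbors.items():
            j = index.get(partner)
            if j is None:  # partner outside the (training) universe
                continue
            vec[j] = 1.0 if mode == "binary" else score / 1000.0
    return vec


def build_feature_views(
    dataset: KinaseDataset,
    sequences: ProteinSequenceSet,
    ppi: PPINetwork | None = None,
    flank: int = DEFAULT_FLANK,
    ppi_mode: str = "binary",
) -> FeatureViews:
    """Encode every sample of a dataset into the two aligned views.

    All sites of one substrate share the same functional row; the
    functional view is omitted when no PPI network is given.
    """
    missing = sorted(
        {s.substrate_id for s in dataset.samples if s.substrate_id not in sequences}
    )
    if missing:
        raise InputError(f"substrates without sequence: {missing}")
    seq_rows = [
        encode_window(extract_window(sequences[s.substrate_id], s.position, flank))
        for s in dataset.samples
    ]
    seq = np.vstack(seq_rows)
    counts = {"seq": seq.shape[1]}
    func = None
    if ppi is not None:
        cache: dict[str, np.ndarray] = {}
        func_rows = []
        for s in dataset.samples:
            if s.substrate_id not in cache:
                cache[s.substrate_id] = encode_function(s.substrate_id, ppi, ppi_mode)
            func_rows.append(cache[s.substrate_id])
        func = np.vstack(func_rows)
        counts["func"] = func.shape[1]
    return FeatureViews(seq=seq, func=func, feature_counts=counts)
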