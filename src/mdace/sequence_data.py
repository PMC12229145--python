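"""Protein I/O, peptide-window extraction/encoding and per-species dataset assembly.

The prediction unit throughout the package is a fixed-length peptide window
centred on a candidate lysine (K): by default 31 residues spanning offsets
-15..+15, with positions falling outside the protein padded by the
placeholder residue ``X``.  Windows are one-hot encoded over a 21-letter
alphabet (the 20 standard residues in alphabetical order, then ``X``),
giving a 31 x 21 feature matrix per window.

Datasets are species-scoped ("domains"): positives are windows at
experimentally verified acetylation sites, negatives are windows at every
other lysine of the same proteins.  Splitting is stratified by label
(test fraction first, then a validation fraction of the remainder) and each
split may be balanced by seeded down-sampling of its majority class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

#: 20 standard residues in alphabetical one-letter order, then the padding
#: placeholder 'X'.  Column order of every one-hot feature matrix.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY" + "X"

STANDARD_RESIDUES: str = ALPHABET[:-1]

_ALPHABET_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

DEFAULT_FLANK = 15


class SequenceDataError(ValueError):
    """Raised for malformed inputs or contract violations during data assembly."""


# ---------------------------------------------------------------------------
# Core records
# ---------------------------------------------------------------------------

@dataclass
class ProteinRecord:
    """A protein sequence plus its verified acetylation sites (1-based)."""

    id: str
    sequence: str
    positive_sites: set[int] = field(default_factory=set)

    def lysine_positions(self) -> list[int]:
        """All 1-based positions carrying a lysine."""
        return [i + 1 for i, aa in enumerate(self.sequence) if aa == "K"]


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length residue window centred on a candidate site.

    ``origin`` records (protein id, 1-based centre position) so that split
    membership can be checked for leakage.
    """

    residues: str
    label: int
    species: str
    origin: tuple[str, int]

    def __post_init__(self):
        if len(self.residues) % 2 == 0:
            raise SequenceDataError(
                f"window length must be odd, got {len(self.residues)}"
            )
        if self.label not in (0, 1):
            raise SequenceDataError(f"label must be 0 or 1, got {self.label}")


@dataclass
class DatasetConfig:
    """Controls window extraction, splitting and balancing.

    redundancy_filter: ``None`` (keep everything), a collection of protein
    ids to keep (e.g. from an external clustering run), or the tuple
    ``("greedy", threshold)`` selecting the built-in greedy k-mer Jaccard
    filter -- a labelled approximation of percent-identity clustering.
    """

    flank: int = DEFAULT_FLANK
    test_fraction: float = 0.10
    validation_fraction: float = 0.10
    balance: bool = True
    seed: int = 0
    redundancy_filter: object = None

    def __post_init__(self):
        if not (0 < self.test_fraction < 1):
            raise SequenceDataError("test_fraction must lie in (0, 1)")
        if self.flank < 1:
            raise SequenceDataError("flank must be >= 1")


@dataclass
class DomainDataset:
    """Labelled windows for one species, split into train/validation/test."""

    species: str
    train: list[PeptideWindow]
    validation: list[PeptideWindow]
    test: list[PeptideWindow]
    seed: int
    usable: bool = True

    def counts(self, split: str) -> tuple[int, int]:
        """(n_pos, n_neg) for a split name."""
        ws = getattr(self, split)
        n_pos = sum(w.label for w in ws)
        return n_pos, len(ws) - n_pos

    def encoded(self, split: str, alphabet: str = ALPHABET) -> tuple[np.ndarray, np.ndarray]:
        """One-hot arrays (B, W, A) and labels (B,) for a split."""
        ws = getattr(self, split)
        if not ws:
            return np.zeros((0, 0, len(alphabet))), np.zeros(0, dtype=int)
        X = np.stack([encode_window(w.residues, alphabet) for w in ws])
        y = np.array([w.label for w in ws], dtype=int)
        return X, y

    # -- persistence (plain-text window table + YAML manifest) --------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for split in ("train", "validation", "test"):
            for w in getattr(self, split):
                rows.append(
                    dict(species=w.species, window=w.residues, label=w.label,
                         split=split, protein_id=w.origin[0], position=w.origin[1])
                )
        return pd.DataFrame(rows, columns=["species", "window", "label",
                                           "split", "protein_id", "position"])

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "windows.csv", index=False)
        manifest = {
            "species": self.species,
            "seed": int(self.seed),
            "alphabet": ALPHABET,
            "usable": bool(self.usable),
            "counts": {s: list(map(int, self.counts(s)))
                       for s in ("train", "validation", "test")},
        }
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
        return out / "windows.csv"

    @classmethod
    def load(cls, in_dir: str | Path) -> "DomainDataset":
        in_dir = Path(in_dir)
        df = pd.read_csv(in_dir / "windows.csv")
        manifest = yaml.safe_load((in_dir / "manifest.yaml").read_text())
        splits: dict[str, list[PeptideWindow]] = {"train": [], "validation": [], "test": []}
        for row in df.itertuples(index=False):
            splits[row.split].append(
                PeptideWindow(row.window, int(row.label), str(row.species),
                              (str(row.protein_id), int(row.position)))
            )
        return cls(species=manifest["species"], seed=int(manifest["seed"]),
                   usable=bool(manifest.get("usable", True)), **splits)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def normalize_sequence(seq: str) -> str:
    """Uppercase and map residues outside the 20 standard codes to 'X'."""
    seq = seq.upper()
    return "".join(c if c in STANDARD_RESIDUES else "X" for c in seq)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA into :class:`ProteinRecord` objects.

    Sequences are normalised (uppercased, non-standard residues mapped to
    'X'); record order is preserved; positive-site sets start empty.
    """
    records = []
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise SequenceDataError(f"record {idx}: empty FASTA header")
        seq = str(rec.seq)
        if not seq:
            raise SequenceDataError(f"record {idx} ({rec.id}): empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=normalize_sequence(seq)))
    return records


def load_annotations(path: str | Path,
                     proteins: Sequence[ProteinRecord]) -> tuple[list[ProteinRecord], int]:
    """Attach (protein id, 1-based position) site annotations to proteins.

    Annotations at non-lysine residues are rejected (counted, not raised);
    positions outside the sequence raise; unknown protein ids raise.

    Returns the protein list (mutated in place) and the reject count.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        id_col, pos_col = cols["protein_id"], cols["position"]
    except KeyError:
        raise SequenceDataError(
            f"annotation file must have columns 'protein_id' and 'position'; got {list(df.columns)}"
        )
    by_id = {p.id: p for p in proteins}
    unknown = sorted(set(df[id_col].astype(str)) - set(by_id))
    if unknown:
        raise SequenceDataError(f"annotations reference unknown protein ids: {unknown}")
    rejected = 0
    for pid, pos in zip(df[id_col].astype(str), df[pos_col].astype(int)):
        prot = by_id[pid]
        if not (1 <= pos <= len(prot.sequence)):
            raise SequenceDataError(
                f"annotation ({pid}, {pos}) out of range for sequence of length {len(prot.sequence)}"
            )
        if prot.sequence[pos - 1] != "K":
            rejected += 1
            continue
        prot.positive_sites.add(pos)
    return list(proteins), rejected


# ---------------------------------------------------------------------------
# Windows and encoding
# ---------------------------------------------------------------------------

def extract_window(sequence: str, position: int, flank: int = DEFAULT_FLANK,
                   require_center_k: bool = True) -> str:
    """Cut the residue window covering offsets -flank..+flank around ``position``.

    ``position`` is 1-based; out-of-range offsets are padded with 'X'.  The
    centre must be a lysine unless ``require_center_k`` is disabled (used by
    the simulator's stress tests only).
    """
    if not (1 <= position <= len(sequence)):
        raise SequenceDataError(f"position {position} outside sequence of length {len(sequence)}")
    center = sequence[position - 1]
    if require_center_k and center != "K":
        raise SequenceDataError(f"centre residue at position {position} is '{center}', not 'K'")
    chars = []
    for pos in range(position - flank, position + flank + 1):
        chars.append(sequence[pos - 1] if 1 <= pos <= len(sequence) else "X")
    return "".join(chars)


def encode_window(residues: str, alphabet: str = ALPHABET) -> np.ndarray:
    """One-hot encode a window as a (len(residues), len(alphabet)) float array."""
    A = len(alphabet)
    index = _ALPHABET_INDEX if alphabet == ALPHABET else {a: i for i, a in enumerate(alphabet)}
    out = np.zeros((len(residues), A))
    for r, aa in enumerate(residues):
        j = index.get(aa)
        if j is None:
            raise SequenceDataError(f"character {aa!r} at window position {r} not in alphabet")
        out[r, j] = 1.0
    return out


def decode_window(matrix: np.ndarray, alphabet: str = ALPHABET) -> str:
    """Inverse of :func:`encode_window` for valid one-hot input."""
    if matrix.ndim != 2 or matrix.shape[1] != len(alphabet):
        raise SequenceDataError(f"expected (W, {len(alphabet)}) matrix, got {matrix.shape}")
    return "".join(alphabet[j] for j in np.argmax(matrix, axis=1))


# ---------------------------------------------------------------------------
# Redundancy filtering (approximate stand-in for external clustering)
# ---------------------------------------------------------------------------

def greedy_redundancy_filter(proteins: Sequence[ProteinRecord],
                             threshold: float = 0.4, k: int = 5) -> list[ProteinRecord]:
    """Greedy k-mer Jaccard filter, an *approximation* of identity clustering.

    Proteins are scanned in input order; one is kept if its k-mer Jaccard
    similarity to every previously kept protein is below ``threshold``
    (mapped loosely from a percent-identity cutoff).  This is not a
    replacement for a real clustering tool; it exists so pipelines without
    one still remove near-duplicates.
    """
    kept: list[ProteinRecord] = []
    kmer_sets: list[set[str]] = []
    for prot in proteins:
        kmers = {prot.sequence[i:i + k] for i in range(max(1, len(prot.sequence) - k + 1))}
        redundant = False
        for other in kmer_sets:
            union = len(kmers | other)
            if union and len(kmers & other) / union >= threshold:
                redundant = True
                break
        if not redundant:
            kept.append(prot)
            kmer_sets.append(kmers)
    return kept


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def _split_counts(n: int, fraction: float) -> int:
    return int(round(n * fraction))


def _stratified_split(windows: list[PeptideWindow], config: DatasetConfig,
                      rng: np.random.Generator) -> tuple[list, list, list]:
    """Label-stratified test split, then validation split of the remainder."""
    train: list[PeptideWindow] = []
    val: list[PeptideWindow] = []
    test: list[PeptideWindow] = []
    for label in (1, 0):
        group = [w for w in windows if w.label == label]
        order = rng.permutation(len(group))
        group = [group[i] for i in order]
        n_test = _split_counts(len(group), config.test_fraction)
        test.extend(group[:n_test])
        rest = group[n_test:]
        n_val = _split_counts(len(rest), config.validation_fraction)
        val.extend(rest[:n_val])
        train.extend(rest[n_val:])
    return train, val, test


def _balance(windows: list[PeptideWindow], rng: np.random.Generator) -> list[PeptideWindow]:
    """Down-sample the majority class to the minority count (without replacement)."""
    pos = [w for w in windows if w.label == 1]
    neg = [w for w in windows if w.label == 0]
    n = min(len(pos), len(neg))
    if len(pos) > n:
        pos = [pos[i] for i in rng.choice(len(pos), size=n, replace=False)]
    if len(neg) > n:
        neg = [neg[i] for i in rng.choice(len(neg), size=n, replace=False)]
    return pos + neg


def build_species_dataset(proteins: Sequence[ProteinRecord], species: str,
                          config: DatasetConfig | None = None) -> DomainDataset:
    """Assemble a species dataset from annotated proteins.

    Positives are windows at annotated acetylation sites; negatives are
    windows at every other lysine of the retained proteins.  The test
    fraction of each class is drawn first (seeded), a validation fraction of
    the remainder second, and each split is then independently balanced by
    down-sampling its majority class when ``config.balance`` is set.
    """
    config = config or DatasetConfig()
    proteins = list(proteins)
    if config.redundancy_filter is not None:
        rf = config.redundancy_filter
        if isinstance(rf, tuple) and rf and rf[0] == "greedy":
            proteins = greedy_redundancy_filter(proteins, threshold=float(rf[1]))
        else:  # precomputed keep-list of protein ids
            keep = set(rf)
            proteins = [p for p in proteins if p.id in keep]

    windows: list[PeptideWindow] = []
    for prot in proteins:
        for pos in prot.lysine_positions():
            residues = extract_window(prot.sequence, pos, config.flank)
            label = 1 if pos in prot.positive_sites else 0
            windows.append(PeptideWindow(residues, label, species, (prot.id, pos)))

    n_pos = sum(w.label for w in windows)
    if n_pos == 0:
        raise SequenceDataError(f"species {species!r} has zero positive sites")
    usable = True
    if n_pos < 2:
        warnings.warn(f"species {species!r} has fewer than 2 positives; dataset flagged unusable")
        usable = False

    rng = np.random.default_rng(config.seed)
    train, val, test = _stratified_split(windows, config, rng)
    if config.balance:
        train = _balance(train, rng)
        val = _balance(val, rng)
        test = _balance(test, rng)
    return DomainDataset(species=species, train=train, validation=val,
                         test=test, seed=config.seed, usable=usable)
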