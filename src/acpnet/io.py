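"""Reading and validating peptide sequences, labels and secondary-structure profiles.

Peptides arrive as FASTA (labels either as the final ``|``-delimited header
token or in a sidecar two-column TSV); per-residue 3-state secondary-structure
probabilities arrive as a TSV with one row per residue, as emitted by an
external predictor such as SPIDER3.  This module pairs the two into a
:class:`LabeledDataset` ready for encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Internal secondary-structure state order. Fixed as (helix, strand, coil)
#: regardless of upstream predictor labelling conventions.
STRUCTURE_STATES = ("helix", "strand", "coil")

STRUCTURE_COLUMNS = ["id", "residue_index", "p_helix", "p_strand", "p_coil"]


class DataError(ValueError):
    """Base class for dataset validation failures."""


class DuplicateIdError(DataError):
    """Two records share an id within one dataset."""


class LabelParseError(DataError):
    """A label token could not be parsed as 0/1."""


class EmptySequenceError(DataError):
    """A FASTA entry carries no residues."""


class ProfileError(DataError):
    """A structure profile violates its contract (contiguity, probabilities)."""


class LengthMismatchError(DataError):
    """Profile length differs from the paired sequence length."""


class EmptyDatasetError(DataError):
    """An operation received or produced a dataset with no records."""


@dataclass(frozen=True)
class PeptideRecord:
    """An identified amino-acid sequence with an optional binary label.

    ``label`` is 1 for anticancer peptides (positives), 0 for non-ACPs,
    ``None`` when unlabeled.
    """

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise EmptySequenceError(f"record {self.id!r} has an empty sequence")
        if self.label is not None and self.label not in (0, 1):
            raise LabelParseError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class StructureProfile:
    """Per-residue (helix, strand, coil) probabilities for one peptide.

    ``probs`` has shape (L, 3); each row is renormalized to sum to 1.
    """

    id: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 3:
            raise ProfileError(f"profile {self.id!r}: expected (L, 3) array, got {probs.shape}")
        if probs.shape[0] == 0:
            raise ProfileError(f"profile {self.id!r}: zero rows")
        if np.any(probs < -1e-6):
            raise ProfileError(f"profile {self.id!r}: negative probability beyond tolerance")
        sums = probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            # tolerate mild drift from upstream predictors, renormalize below
            bad = np.abs(sums - 1.0) > 0.5
            if np.any(bad):
                raise ProfileError(
                    f"profile {self.id!r}: row sums far from 1 (min {sums.min():.3f}, max {sums.max():.3f})"
                )
        probs = np.clip(probs, 0.0, 1.0)
        probs = probs / probs.sum(axis=1, keepdims=True)
        object.__setattr__(self, "probs", probs)

    def __len__(self) -> int:
        return self.probs.shape[0]


@dataclass
class LabeledDataset:
    """Labeled peptides plus (optionally) their structure profiles."""

    records: list[PeptideRecord]
    profiles: dict[str, StructureProfile] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise DuplicateIdError("duplicate record ids in dataset")
        known = set(ids)
        for pid, prof in self.profiles.items():
            if pid not in known:
                raise ProfileError(f"profile {pid!r} has no matching record")
            seq_len = len(next(r.sequence for r in self.records if r.id == pid))
            if len(prof) != seq_len:
                raise LengthMismatchError(
                    f"profile {pid!r} has length {len(prof)} but sequence has {seq_len}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    @property
    def has_structure(self) -> bool:
        return len(self.profiles) == len(self.records) and len(self.records) > 0

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        recs = [self.records[i] for i in indices]
        profs = {r.id: self.profiles[r.id] for r in recs if r.id in self.profiles}
        return LabeledDataset(recs, profs)


def _parse_label_token(token: str, record_id: str) -> int:
    if token not in ("0", "1"):
        raise LabelParseError(f"record {record_id!r}: label token {token!r} is not 0 or 1")
    return int(token)


def read_fasta(
    path: str | Path,
    label_policy: str = "header_token",
    sidecar: str | Path | None = None,
) -> list[PeptideRecord]:
    """Read peptides from FASTA, order preserved, sequences uppercased.

    label_policy:
      * ``header_token`` — the final ``|``-delimited token of each header is
        the 0/1 label (e.g. ``>pep1|1``).
      * ``sidecar_table`` — labels come from a two-column ``id\\tlabel`` TSV
        given as ``sidecar``.
      * ``unlabeled`` — records carry no labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    if label_policy not in ("header_token", "sidecar_table", "unlabeled"):
        raise ValueError(f"unknown label_policy {label_policy!r}")

    sidecar_labels: dict[str, int] = {}
    if label_policy == "sidecar_table":
        if sidecar is None:
            raise ValueError("label_policy='sidecar_table' requires a sidecar path")
        table = pd.read_csv(sidecar, sep="\t", header=None, names=["id", "label"], dtype=str)
        for _, row in table.iterrows():
            sidecar_labels[str(row["id"])] = _parse_label_token(str(row["label"]), str(row["id"]))

    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description or entry.id
        seq = str(entry.seq).upper()
        if label_policy == "header_token":
            parts = header.split("|")
            if len(parts) < 2:
                raise LabelParseError(f"header {header!r} has no |-delimited label token")
            rec_id = "|".join(parts[:-1])
            label: Optional[int] = _parse_label_token(parts[-1].strip(), rec_id)
        elif label_policy == "sidecar_table":
            rec_id = header.split()[0]
            if rec_id not in sidecar_labels:
                raise LabelParseError(f"record {rec_id!r} missing from sidecar label table")
            label = sidecar_labels[rec_id]
        else:
            rec_id = header.split()[0]
            label = None
        if rec_id in seen:
            raise DuplicateIdError(f"duplicate FASTA id {rec_id!r}")
        seen.add(rec_id)
        if len(seq) == 0:
            raise EmptySequenceError(f"record {rec_id!r} has an empty sequence")
        records.append(PeptideRecord(id=rec_id, sequence=seq, label=label))

    if not records:
        logger.warning("FASTA file %s contained no entries", path)
    return records


def write_fasta(records: Sequence[PeptideRecord], path: str | Path) -> None:
    """Write records as header-token FASTA (``>id|label``; bare id if unlabeled)."""
    entries = []
    for rec in records:
        name = rec.id if rec.label is None else f"{rec.id}|{rec.label}"
        entries.append(SeqRecord(Seq(rec.sequence), id=name, description=""))
    SeqIO.write(entries, str(path), "fasta")


def read_structure_profiles(path: str | Path) -> dict[str, StructureProfile]:
    """Read per-residue structure probabilities from TSV.

    Expected columns: ``id, residue_index, p_helix, p_strand, p_coil`` with
    residue_index 1-based and contiguous per id.  Probabilities are clipped to
    [0, 1] and renormalized per residue.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure profile file not found: {path}")
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in STRUCTURE_COLUMNS if c not in table.columns]
    if missing:
        raise ProfileError(f"structure TSV missing columns: {missing}")

    profiles: dict[str, StructureProfile] = {}
    for pid, group in table.groupby("id", sort=False):
        idx = group["residue_index"].to_numpy(dtype=int)
        order = np.argsort(idx)
        idx = idx[order]
        if len(idx) == 0:
            raise ProfileError(f"profile {pid!r}: zero rows")
        expected = np.arange(1, len(idx) + 1)
        if not np.array_equal(idx, expected):
            raise ProfileError(f"profile {pid!r}: residue indices not contiguous from 1")
        probs = group[["p_helix", "p_strand", "p_coil"]].to_numpy(dtype=float)[order]
        profiles[str(pid)] = StructureProfile(id=str(pid), probs=probs)
    return profiles


def write_structure_profiles(profiles: Mapping[str, StructureProfile], path: str | Path) -> None:
    """Write profiles in the TSV dialect accepted by :func:`read_structure_profiles`."""
    rows = []
    for pid, prof in profiles.items():
        for i, (h, e, c) in enumerate(prof.probs, start=1):
            rows.append((pid, i, h, e, c))
    pd.DataFrame(rows, columns=STRUCTURE_COLUMNS).to_csv(path, sep="\t", index=False)


def build_dataset(
    records: Sequence[PeptideRecord],
    profiles: Mapping[str, StructureProfile] | None = None,
    require_structure: bool = False,
) -> tuple[LabeledDataset, int]:
    """Pair records with profiles; returns (dataset, n_dropped).

    With ``require_structure``, records lacking a matching-length profile are
    dropped (mirroring upstream removal of peptides the structure predictor
    could not handle) and the dropped count is reported.
    """
    profiles = dict(profiles or {})
    if require_structure:
        kept, used = [], {}
        for rec in records:
            prof = profiles.get(rec.id)
            if prof is None:
                continue
            if len(prof) != len(rec.sequence):
                raise LengthMismatchError(
                    f"profile {rec.id!r} has length {len(prof)} "
                    f"but sequence has {len(rec.sequence)}"
                )
            kept.append(rec)
            used[rec.id] = prof
        n_dropped = len(records) - len(kept)
        if not kept:
            raise EmptyDatasetError("all records dropped: no structure profiles matched")
        if n_dropped:
            logger.info("dropped %d record(s) lacking structure profiles", n_dropped)
        return LabeledDataset(list(kept), used), n_dropped

    used = {rid: p for rid, p in profiles.items() if rid in {r.id for r in records}}
    return LabeledDataset(list(records), used), 0
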