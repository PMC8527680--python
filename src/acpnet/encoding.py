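"""One-hot sequence and structure-profile encoding into padded, masked tensors.

Each residue is encoded as a length-20 one-hot vector (a peptide of length L
becomes an L x 20 binary matrix) and each residue's secondary-structure state
probabilities as a 3-vector (helix, strand, coil), giving an L x 3 real
matrix.  Variable-length peptides are post-padded with zero rows to a common
``max_len`` and accompanied by a binary validity mask consumed downstream by
the attention and recurrent branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AMINO_ACIDS, LabeledDataset, StructureProfile

#: Frozen alphabetical ordering of the 20 canonical residues; the one-hot
#: column index of residue ``a`` is ``AMINO_ACIDS.index(a)``.
ALPHABET_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Hard cap on peptide length: anticancer peptides are short (roughly 5-50
#: residues), so anything longer signals a data problem and is rejected
#: rather than truncated.
MAX_PEPTIDE_LEN = 50


class InvalidResidueError(ValueError):
    """Sequence contains a character outside the 20-letter alphabet (strict mode)."""


class OverlongSequenceError(ValueError):
    """Sequence or profile exceeds the configured maximum length."""


@dataclass
class EncodedBatch:
    """Padded numeric tensors for a batch of N peptides.

    seq_onehot : (N, Lmax, 20) binary
    struct_feats : (N, Lmax, 3) real, all-zero when structure is absent
    mask : (N, Lmax) binary validity mask (1 = real residue)
    labels : (N,) binary, or None for unlabeled batches
    lengths : (N,) int
    """

    seq_onehot: np.ndarray
    struct_feats: np.ndarray
    mask: np.ndarray
    labels: np.ndarray | None
    lengths: np.ndarray
    ids: list[str]
    has_structure: bool

    @property
    def n(self) -> int:
        return self.seq_onehot.shape[0]

    @property
    def max_len(self) -> int:
        return self.seq_onehot.shape[1]

    def subset(self, indices) -> "EncodedBatch":
        idx = np.asarray(indices)
        return EncodedBatch(
            seq_onehot=self.seq_onehot[idx],
            struct_feats=self.struct_feats[idx],
            mask=self.mask[idx],
            labels=None if self.labels is None else self.labels[idx],
            lengths=self.lengths[idx],
            ids=[self.ids[i] for i in idx],
            has_structure=self.has_structure,
        )


def one_hot_encode(
    sequence: str,
    max_len: int,
    strict: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode one sequence as an (max_len, 20) one-hot matrix plus validity mask.

    In strict mode a residue outside the canonical alphabet raises
    :class:`InvalidResidueError`; in lenient mode it yields an all-zero row
    (still masked in).
    """
    L = len(sequence)
    if L > max_len:
        raise OverlongSequenceError(f"sequence length {L} exceeds max_len {max_len}")
    onehot = np.zeros((max_len, 20), dtype=np.float64)
    mask = np.zeros(max_len, dtype=np.float64)
    for t, aa in enumerate(sequence):
        col = ALPHABET_INDEX.get(aa)
        if col is None:
            if strict:
                raise InvalidResidueError(f"invalid residue {aa!r} at position {t}")
        else:
            onehot[t, col] = 1.0
        mask[t] = 1.0
    return onehot, mask


def encode_structure(profile: StructureProfile, max_len: int) -> np.ndarray:
    """Copy a profile's (helix, strand, coil) rows into an (max_len, 3) matrix, zero-padded."""
    L = len(profile)
    if L > max_len:
        raise OverlongSequenceError(f"profile length {L} exceeds max_len {max_len}")
    out = np.zeros((max_len, 3), dtype=np.float64)
    out[:L] = profile.probs
    return out


def batch_encode(
    dataset: LabeledDataset,
    max_len: int | str = "auto",
    strict: bool = True,
) -> EncodedBatch:
    """Encode a whole dataset into an :class:`EncodedBatch`, order preserved.

    ``max_len='auto'`` resolves to the longest sequence present (never above
    :data:`MAX_PEPTIDE_LEN`); an explicit integer is used as given.
    """
    if len(dataset) == 0:
        raise ValueError("cannot encode an empty dataset")
    lengths = np.array([len(r.sequence) for r in dataset.records], dtype=int)
    if max_len == "auto":
        resolved = int(lengths.max())
        if resolved > MAX_PEPTIDE_LEN:
            raise OverlongSequenceError(
                f"dataset contains a {resolved}-residue sequence, above the "
                f"{MAX_PEPTIDE_LEN}-residue cap"
            )
    else:
        resolved = int(max_len)

    n = len(dataset)
    seq = np.zeros((n, resolved, 20), dtype=np.float64)
    struct = np.zeros((n, resolved, 3), dtype=np.float64)
    mask = np.zeros((n, resolved), dtype=np.float64)
    for i, rec in enumerate(dataset.records):
        seq[i], mask[i] = one_hot_encode(rec.sequence, resolved, strict=strict)
        prof = dataset.profiles.get(rec.id)
        if prof is not None:
            struct[i] = encode_structure(prof, resolved)

    labels = None
    if all(r.label is not None for r in dataset.records):
        labels = np.array([r.label for r in dataset.records], dtype=np.float64)

    return EncodedBatch(
        seq_onehot=seq,
        struct_feats=struct,
        mask=mask,
        labels=labels,
        lengths=lengths,
        ids=[r.id for r in dataset.records],
        has_structure=dataset.has_structure,
    )
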