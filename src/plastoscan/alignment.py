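"""Multiple sequence alignment container with source-coordinate tracking.

The alignment is a taxa x columns character matrix over DNA states, IUPAC
ambiguity codes and the gap character '-'.  Characters are stored as small
integer codes; each code maps to a 4-vector of state compatibilities (the
partial-likelihood row used by the pruning algorithm).  An optional
``coords`` track records, for every column, its 1-based position in an
un-trimmed source frame so that trimmed or split alignments can still report
genome-scale coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Character alphabet.  Order matters: the first four codes are the pure
# states A, C, G, T used by the simulators.
_ALPHABET = "ACGTRYSWKMBDHVN-?"
CODE_OF = {c: i for i, c in enumerate(_ALPHABET)}
GAP_CODE = CODE_OF["-"]

_IUPAC_STATES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    "-": "ACGT", "?": "ACGT",
}

#: (n_codes, 4) 0/1 matrix: STATE_MASK[code, j] == 1 iff state j is
#: compatible with the character.  Gaps and '?' are compatible with all.
STATE_MASK = np.zeros((len(_ALPHABET), 4), dtype=np.float64)
for _c, _states in _IUPAC_STATES.items():
    for _s in _states:
        STATE_MASK[CODE_OF[_c], "ACGT".index(_s)] = 1.0

_DECODE = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _c in _ALPHABET:
    _ENCODE[ord(_c)] = CODE_OF[_c]
    _ENCODE[ord(_c.lower())] = CODE_OF[_c]


@dataclass
class Alignment:
    """Taxa x columns character matrix.

    Parameters
    ----------
    taxa
        Ordered, unique taxon names.
    data
        ``(n_taxa, n_columns)`` uint8 matrix of character codes.
    coords
        Optional 1-based source coordinate per column, strictly increasing.
    partitions
        Named half-open column intervals ``{name: [(start, stop), ...]}``
        in 0-based alignment-column space.
    """

    taxa: list[str]
    data: np.ndarray
    coords: np.ndarray | None = None
    partitions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-dimensional")
        if len(self.taxa) != self.data.shape[0]:
            raise ValueError("taxa count does not match matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon names must be unique")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.int64)
            if self.coords.shape != (self.data.shape[1],):
                raise ValueError("coords length must equal column count")
            if self.data.shape[1] > 1 and not np.all(np.diff(self.coords) > 0):
                raise ValueError("coords must be strictly increasing")

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def __len__(self) -> int:
        return self.n_columns

    @classmethod
    def from_sequences(
        cls,
        taxa: list[str],
        sequences: list[str],
        coords: np.ndarray | None = None,
    ) -> "Alignment":
        if len(taxa) != len(sequences):
            raise ValueError("one sequence per taxon required")
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise ValueError("all rows must have equal length")
        raw = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
        data = _ENCODE[raw].reshape(len(taxa), -1)
        if np.any(data == 255):
            bad = chr(raw[np.argmax(_ENCODE[raw] == 255)])
            raise ValueError(f"unsupported character {bad!r} in alignment")
        return cls(list(taxa), data, coords=coords)

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]

    def sequence(self, taxon: str) -> str:
        return _DECODE[self.row(taxon)].tobytes().decode()

    def take_columns(self, index: np.ndarray) -> "Alignment":
        """Column subset (order-preserving), carrying source coordinates.

        When no source map exists yet, the subset records its original
        1-based column positions so provenance survives further splitting.
        """
        index = np.asarray(index)
        coords = self.effective_coords()[index]
        return Alignment(list(self.taxa), self.data[:, index], coords=coords)

    def effective_coords(self) -> np.ndarray:
        """Source coordinates, defaulting to 1..L when no map is present."""
        if self.coords is not None:
            return self.coords
        return np.arange(1, self.n_columns + 1, dtype=np.int64)

    def gap_mask(self) -> np.ndarray:
        """Boolean (n_taxa, L) mask of gap characters."""
        return self.data == GAP_CODE


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file (gap '-', case-insensitive)."""
    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper().replace(".", "-"))
    if not names:
        raise ValueError(f"no sequences found in {path}")
    return Alignment.from_sequences(names, seqs)


def write_fasta(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(aln.sequence(t)), id=t, description="") for t in aln.taxa
    ]
    SeqIO.write(records, str(path), "fasta")
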