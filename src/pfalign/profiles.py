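"""Profile (PSSM) and pairwise-alignment containers and file I/O.

A *profile* is a protein sequence together with one 20-dimensional
position-specific scoring vector (PSSV) per site, the per-site likelihood of
observing each amino acid.  Profiles are read from the PSI-BLAST/DELTA-BLAST
ASCII PSSM dialect; the PSSV values are the weighted-observed-percentage block
scaled to [0, 1] (the log-odds block is parsed for validation but not used).

All site indices are 0-based in memory; files render them 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical PSI-BLAST residue column order, fixed for every profile in a run.
RESIDUE_ORDER = "ARNDCQEGHILKMFPSTWYV"

GAP = None  # gap marker inside alignment columns


class ProfileError(ValueError):
    """Malformed or invalid profile data."""


class AlignmentFormatError(ValueError):
    """Malformed pairwise alignment data."""


@dataclass(frozen=True)
class Profile:
    """A protein profile: sequence plus an L x 20 matrix of PSSVs in [0, 1].

    Invariants are enforced at construction; downstream code may assume a
    validated object.
    """

    id: str
    sequence: str
    vectors: np.ndarray
    column_order: str = RESIDUE_ORDER

    def __post_init__(self):
        vectors = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", vectors)
        if len(self.sequence) < 1:
            raise ProfileError(f"profile {self.id!r}: empty sequence")
        if vectors.ndim != 2 or vectors.shape != (len(self.sequence), 20):
            raise ProfileError(
                f"profile {self.id!r}: vectors shape {vectors.shape} does not "
                f"match sequence length {len(self.sequence)} x 20"
            )
        if not np.isfinite(vectors).all():
            raise ProfileError(f"profile {self.id!r}: non-finite PSSV element")
        if (vectors < 0).any() or (vectors > 1).any():
            raise ProfileError(f"profile {self.id!r}: PSSV element outside [0, 1]")
        if self.column_order != RESIDUE_ORDER:
            raise ProfileError(
                f"profile {self.id!r}: column order {self.column_order!r} is not "
                f"the canonical {RESIDUE_ORDER!r}"
            )
        if not all("A" <= c <= "Z" for c in self.sequence):
            raise ProfileError(f"profile {self.id!r}: sequence has non-letter residue")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment as an ordered list of columns.

    Each column is ``(i, j)`` (sites aligned), ``(i, None)`` (gap in B) or
    ``(None, j)`` (gap in A), with 0-based site indices.  Every site of each
    profile appears exactly once and in increasing order (full coverage).
    """

    id_a: str
    id_b: str
    columns: Tuple[Tuple[Optional[int], Optional[int]], ...]

    def __post_init__(self):
        cols = tuple((i, j) for i, j in self.columns)
        object.__setattr__(self, "columns", cols)
        i_seen = [i for i, _ in cols if i is not None]
        j_seen = [j for _, j in cols if j is not None]
        if any(i is None and j is None for i, j in cols):
            raise AlignmentFormatError("column with gaps in both sequences")
        if i_seen != list(range(len(i_seen))) or j_seen != list(range(len(j_seen))):
            raise AlignmentFormatError(
                "site indices must cover 0..L-1 exactly once, in increasing order"
            )
        if not i_seen and not j_seen:
            raise AlignmentFormatError("empty alignment")

    @property
    def length_a(self) -> int:
        return sum(1 for i, _ in self.columns if i is not None)

    @property
    def length_b(self) -> int:
        return sum(1 for _, j in self.columns if j is not None)

    def gapped_strings(self, seq_a: str, seq_b: str) -> Tuple[str, str]:
        """Render the alignment as two gapped strings over the given sequences."""
        if len(seq_a) != self.length_a or len(seq_b) != self.length_b:
            raise AlignmentFormatError("sequence lengths do not match alignment")
        row_a = "".join("-" if i is None else seq_a[i] for i, _ in self.columns)
        row_b = "".join("-" if j is None else seq_b[j] for _, j in self.columns)
        return row_a, row_b


def alignment_from_gapped(
    id_a: str, id_b: str, row_a: str, row_b: str
) -> PairwiseAlignment:
    """Build a PairwiseAlignment from two equal-length gapped strings."""
    if len(row_a) != len(row_b):
        raise AlignmentFormatError(
            f"gapped rows differ in length: {len(row_a)} vs {len(row_b)}"
        )
    columns = []
    i = j = 0
    for ca, cb in zip(row_a, row_b):
        gap_a, gap_b = ca == "-", cb == "-"
        if gap_a and gap_b:
            raise AlignmentFormatError("column with gaps in both sequences")
        columns.append((None if gap_a else i, None if gap_b else j))
        if not gap_a:
            i += 1
        if not gap_b:
            j += 1
    return PairwiseAlignment(id_a=id_a, id_b=id_b, columns=tuple(columns))


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM dialect
# ---------------------------------------------------------------------------

_HEADER_COMMENT = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative weight "
    "of gapless real matches to pseudocounts"
)


def read_pssm(path) -> Profile:
    """Read a PSI-BLAST ASCII PSSM file into a Profile.

    The PSSVs are the weighted-observed-percentage block divided by 100; the
    log-odds block is validated for field count but otherwise ignored.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    seq_chars = []
    rows = []
    in_data = False
    for lineno, line in enumerate(lines, start=1):
        fields = line.split()
        if not in_data:
            # The residue header line contains 40 single-letter columns.
            if len(fields) == 40 and all(len(f) == 1 and f.isalpha() for f in fields):
                in_data = True
            continue
        if not fields:
            continue
        if not fields[0].isdigit():
            break  # trailing statistics block (K/Lambda lines)
        if len(fields) not in (42, 44):
            raise ProfileError(
                f"{path}:{lineno}: expected 42 or 44 fields "
                f"(index, residue, 20 log-odds, 20 percentages[, 2 stats]), "
                f"got {len(fields)}"
            )
        residue = fields[1]
        try:
            [int(x) for x in fields[2:22]]  # log-odds block: validated, unused
            percents = [float(x) for x in fields[22:42]]
        except ValueError as exc:
            raise ProfileError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
        if any(p < 0 or p > 100 for p in percents):
            raise ProfileError(
                f"{path}:{lineno}: weighted observed percentage outside [0, 100]"
            )
        seq_chars.append(residue)
        rows.append([p / 100.0 for p in percents])
    if not rows:
        raise ProfileError(f"{path}: no PSSM data rows found")
    return Profile(id=path.stem, sequence="".join(seq_chars), vectors=np.array(rows))


def _fmt_percent(value: float) -> str:
    pct = value * 100.0
    if math.isclose(pct, round(pct), abs_tol=5e-7):
        return str(int(round(pct)))
    return f"{pct:.2f}"


def write_pssm(profile: Profile, path) -> None:
    """Write a Profile in the ASCII dialect read by :func:`read_pssm`.

    Percentages are emitted with two decimals (integers without a decimal
    point), so a read/write round trip is exact to 0.01 percentage points.
    The log-odds block is written as zeros.
    """
    path = Path(path)
    out = ["", _HEADER_COMMENT]
    header = "            " + "   ".join(RESIDUE_ORDER) + "     " + "   ".join(RESIDUE_ORDER)
    out.append(header)
    for idx, (res, row) in enumerate(zip(profile.sequence, profile.vectors), start=1):
        logodds = " ".join(["0"] * 20)
        pcts = " ".join(_fmt_percent(v) for v in row)
        out.append(f"{idx:5d} {res}  {logodds}  {pcts}  0.00 0.00")
    out.append("")
    path.write_text("\n".join(out))


# ---------------------------------------------------------------------------
# Gapped pairwise FASTA
# ---------------------------------------------------------------------------

def read_pairwise_fasta_alignment(path) -> PairwiseAlignment:
    """Read a 2-record gapped FASTA file as a PairwiseAlignment."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise AlignmentFormatError(
            f"{path}: expected exactly 2 records, found {len(records)}"
        )
    a, b = records
    if len(a.seq) != len(b.seq):
        raise AlignmentFormatError(
            f"{path}: aligned lengths differ ({len(a.seq)} vs {len(b.seq)})"
        )
    return alignment_from_gapped(a.id, b.id, str(a.seq), str(b.seq))


def write_pairwise_fasta_alignment(
    alignment: PairwiseAlignment, seq_a: str, seq_b: str, path
) -> None:
    """Write a PairwiseAlignment as gapped pairwise FASTA."""
    row_a, row_b = alignment.gapped_strings(seq_a, seq_b)
    records = [
        SeqRecord(Seq(row_a), id=alignment.id_a, description=""),
        SeqRecord(Seq(row_b), id=alignment.id_b, description=""),
    ]
    SeqIO.write(records, str(path), "fasta")


def check_alignment_matches_profiles(
    alignment: PairwiseAlignment, profile_a: Profile, profile_b: Profile
) -> None:
    """Verify that ungapping each alignment row yields the profile sequences."""
    if alignment.length_a != len(profile_a) or alignment.length_b != len(profile_b):
        raise AlignmentFormatError(
            "alignment does not cover the profiles "
            f"({alignment.length_a} vs {len(profile_a)}, "
            f"{alignment.length_b} vs {len(profile_b)})"
        )
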