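"""Pairwise global sequence alignment and derived agreement statistics.

Alignment uses affine-gap Needleman-Wunsch via Biopython's
``PairwiseAligner`` with ClustalW-like defaults (BLOSUM62, gap open 10,
gap extend 0.5).  On top of the alignment this module computes percent
identity (the statistic used to judge whether a template is close enough
for comparative modeling) and the agreement of aligned secondary-structure
states (H/E/C after collapsing all non-helix, non-strand states to coil).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align as _bio_align
from Bio.Align import substitution_matrices as _submat

__all__ = [
    "Alignment",
    "global_align",
    "percent_identity",
    "ss_agreement",
    "read_fasta",
]

GAP = None

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class Alignment:
    """A gapped pairing of two sequences.

    ``pairs`` holds per-column index pairs ``(i, j)`` into the two
    sequences; a gap is ``None``.  No column is a double gap and indices
    increase strictly within each sequence.
    """

    seq_a: str
    seq_b: str
    pairs: list[tuple[int | None, int | None]]
    score: float
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    identity_denominator: str = "aligned_columns"

    def __post_init__(self) -> None:
        last_a = last_b = -1
        for i, j in self.pairs:
            if i is None and j is None:
                raise ValueError("double-gap column")
            if i is not None:
                if i <= last_a:
                    raise ValueError("indices into sequence A not increasing")
                last_a = i
            if j is not None:
                if j <= last_b:
                    raise ValueError("indices into sequence B not increasing")
                last_b = j

    def aligned_pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in self.pairs if i is not None and j is not None]


def _sanitize(seq: str, treat_unknown_as_x: bool) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    out = []
    for c in seq:
        if c in STANDARD_AA or c == "X":
            out.append(c)
        elif treat_unknown_as_x:
            out.append("X")
        else:
            raise ValueError(f"unknown sequence letter {c!r}")
    return "".join(out)


def global_align(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    treat_unknown_as_x: bool = True,
) -> Alignment:
    """Optimal global alignment under affine gap scoring.

    A gap run of length L costs ``gap_open + (L - 1) * gap_extend``;
    terminal gaps are penalized like internal ones.  The aligner's first
    optimal traceback is taken, which is deterministic for fixed inputs.
    """
    sa = _sanitize(seq_a, treat_unknown_as_x)
    sb = _sanitize(seq_b, treat_unknown_as_x)
    aligner = _bio_align.PairwiseAligner()
    aligner.substitution_matrix = _submat.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = "global"
    best = aligner.align(sa, sb)[0]

    pairs: list[tuple[int | None, int | None]] = []
    pa = pb = 0
    for (a_start, a_end), (b_start, b_end) in zip(*best.aligned):
        while pa < a_start:
            pairs.append((pa, None))
            pa += 1
        while pb < b_start:
            pairs.append((None, pb))
            pb += 1
        for k in range(a_end - a_start):
            pairs.append((a_start + k, b_start + k))
        pa, pb = a_end, b_end
    while pa < len(sa):
        pairs.append((pa, None))
        pa += 1
    while pb < len(sb):
        pairs.append((None, pb))
        pb += 1

    return Alignment(
        seq_a=sa,
        seq_b=sb,
        pairs=pairs,
        score=float(best.score),
        matrix_name=matrix,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def percent_identity(aln: Alignment) -> float:
    """100 x identical aligned pairs / aligned non-gap columns."""
    aligned = aln.aligned_pairs()
    if not aligned:
        raise ValueError("alignment has no aligned (non-gap) columns")
    same = sum(1 for i, j in aligned if aln.seq_a[i] == aln.seq_b[j])
    return 100.0 * same / len(aligned)


def _collapse(ss: str) -> str:
    return "".join(c if c in "HE" else "C" for c in ss.upper())


def ss_agreement(ss_a: str, ss_b: str, aln: Alignment) -> float:
    """Percent of aligned columns whose secondary-structure class matches.

    States outside H (helix) and E (strand) collapse to C (coil) before
    comparison, so any coil/turn/bend notation is treated uniformly.
    """
    if len(ss_a) != len(aln.seq_a) or len(ss_b) != len(aln.seq_b):
        raise ValueError("secondary-structure string length mismatch with sequences")
    ca, cb = _collapse(ss_a), _collapse(ss_b)
    aligned = aln.aligned_pairs()
    if not aligned:
        raise ValueError("alignment has no aligned columns")
    same = sum(1 for i, j in aligned if ca[i] == cb[j])
    return 100.0 * same / len(aligned)


def read_fasta(path: str) -> dict[str, str]:
    """Minimal FASTA reading via Biopython; returns id -> sequence."""
    from Bio import SeqIO

    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {path!r}")
    return records
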