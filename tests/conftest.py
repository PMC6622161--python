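import math
import random

import pytest
from Bio.Align import substitution_matrices

from lipoclass import AlignmentParams, load_reference_table

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def registry():
    return load_reference_table()


@pytest.fixture(scope="session")
def params():
    return AlignmentParams()


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def brute_force_global_score(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Exhaustive affine-gap global alignment score for tiny sequences.

    Enumerates every monotone alignment path (match / gap-in-b / gap-in-a,
    never a column gapped in both rows), charging gap_open for the first
    position of a gap run and gap_extend for each subsequent one — the
    same convention as the production aligner, but by enumeration rather
    than dynamic programming.
    """
    mat = substitution_matrices.load(matrix_name)
    best = -math.inf

    def rec(i: int, j: int, last: str, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + mat[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, "A", score - (gap_extend if last == "A" else gap_open))
        if j < len(b):
            rec(i, j + 1, "B", score - (gap_extend if last == "B" else gap_open))

    rec(0, 0, "", 0.0)
    return best
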