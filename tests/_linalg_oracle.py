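"""Independent exact row-reduction oracle (fractions only, no sympy).

Used to cross-check the identity-basis engine: rank, left-nullspace
dimension, and span membership are recomputed here from first principles.
"""

from fractions import Fraction


def rref_rank(matrix):
    """Rank of a rational matrix by plain Gauss-Jordan elimination."""
    rows = [[Fraction(x) for x in row] for row in matrix]
    if not rows:
        return 0
    n_cols = len(rows[0])
    rank = 0
    for col in range(n_cols):
        pivot = next((i for i in range(rank, len(rows)) if rows[i][col] != 0), None)
        if pivot is None:
            continue
        rows[rank], rows[pivot] = rows[pivot], rows[rank]
        inv = rows[rank][col]
        rows[rank] = [x / inv for x in rows[rank]]
        for i in range(len(rows)):
            if i != rank and rows[i][col] != 0:
                factor = rows[i][col]
                rows[i] = [a - factor * b for a, b in zip(rows[i], rows[rank])]
        rank += 1
        if rank == len(rows):
            break
    return rank


def left_nullspace_dim(matrix):
    """Dimension of {v : v^T M = 0} = (#rows) - rank(M)."""
    return len(matrix) - rref_rank(matrix)


def in_row_span(vectors, candidate):
    """True iff *candidate* lies in the rational row span of *vectors*."""
    base = [list(v) for v in vectors]
    return rref_rank(base + [list(candidate)]) == rref_rank(base)


def annihilates(vector, matrix):
    """Exact check that vector^T M == 0 using integer arithmetic."""
    n_cols = len(matrix[0])
    for col in range(n_cols):
        if sum(int(c) * int(row[col]) for c, row in zip(vector, matrix)) != 0:
            return False
    return True
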