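"""Non-redundant training-set construction by sequence identity.

To avoid a model being evaluated on genes homologous to its training genes,
the gene set is reduced so that no retained pair exceeds a percent-identity
threshold (default: strictly greater than 30% is redundant).  Removal is
greedy hub removal — repeatedly drop the gene with the most above-threshold
neighbours — which is deterministic and near-optimal; exactness is not
required because the threshold itself is a heuristic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import Align

from .errors import ValidationError

__all__ = ["pairwise_identity", "approximate_identity", "nonredundant_subset"]


def pairwise_identity(sequences: dict[str, str]) -> pd.DataFrame:
    """Global-alignment percent identity matrix for a set of sequences.

    Identity = matched columns / alignment length (gaps count toward the
    length), using a match/mismatch score of 1/0 and affine gap penalties
    (open -2, extend -0.5).  Intended for fixtures and small real sets.
    """
    for gid, seq in sequences.items():
        if not seq:
            raise ValidationError(f"empty sequence for {gid!r}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    ids = sorted(sequences)
    n = len(ids)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(sequences[ids[i]], sequences[ids[j]])[0]
            a, b = str(aln[0]), str(aln[1])
            matches = sum(x == y and x != "-" for x, y in zip(a, b))
            mat[i, j] = mat[j, i] = 100.0 * matches / len(a)
    return pd.DataFrame(mat, index=ids, columns=ids)


def approximate_identity(sequences: dict[str, str]) -> pd.DataFrame:
    """Fast ungapped identity screen for large gene sets.

    Compares sequences head-to-head without alignment: identity =
    100 · (position-wise matches over the shorter length) / longer length.
    This underestimates true identity for related-but-shifted sequences and
    is intended only as a redundancy screen when exact alignment of all
    pairs is impractical; supply a precomputed matrix for real analyses.
    """
    ids = sorted(sequences)
    arrs = {g: np.frombuffer(sequences[g].encode(), dtype=np.uint8) for g in ids}
    n = len(ids)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        ai = arrs[ids[i]]
        for j in range(i + 1, n):
            aj = arrs[ids[j]]
            m = min(ai.size, aj.size)
            matches = int((ai[:m] == aj[:m]).sum())
            mat[i, j] = mat[j, i] = 100.0 * matches / max(ai.size, aj.size)
    return pd.DataFrame(mat, index=ids, columns=ids)


def nonredundant_subset(
    identity: pd.DataFrame,
    threshold_pct: float = 30.0,
    lengths: dict[str, int] | None = None,
) -> list[str]:
    """Greedy maximal subset with no pairwise identity above the threshold.

    Repeatedly removes the gene with the most above-threshold neighbours;
    ties are broken by shorter protein first (when ``lengths`` is supplied),
    then lexicographically smaller id.  A pair at exactly the threshold is
    retained (only strictly greater counts as redundant).  A final pass
    re-adds any removed gene that no longer conflicts with the retained
    set, so the result is maximal: adding back any excluded gene would
    violate the threshold against a retained gene.
    """
    if list(identity.index) != list(identity.columns):
        raise ValidationError("identity matrix index and columns must match")
    vals = identity.to_numpy(float)
    if not np.allclose(vals, vals.T, atol=1e-9):
        raise ValidationError("identity matrix must be symmetric")
    ids = list(identity.index)
    n = len(ids)
    adj = vals > threshold_pct
    np.fill_diagonal(adj, False)
    alive = np.ones(n, dtype=bool)
    lengths = lengths or {}
    while True:
        degrees = (adj & alive[None, :]).sum(axis=1)
        degrees[~alive] = 0
        max_deg = degrees.max()
        if max_deg == 0:
            break
        candidates = np.flatnonzero(degrees == max_deg)
        # drop the shortest protein among ties, then the lexicographically first id
        drop = min(candidates, key=lambda i: (lengths.get(ids[i], 0), ids[i]))
        alive[drop] = False
    # maximality pass: re-add removed genes that no longer conflict
    for i in range(n):
        if not alive[i] and not (adj[i] & alive).any():
            alive[i] = True
    return [ids[i] for i in range(n) if alive[i]]
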