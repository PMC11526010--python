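"""Internal helpers: seeding, amino-acid alphabets, numeric utilities."""

from __future__ import annotations

import numpy as np

#: Canonical 20 amino acids, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: pLDDT value below which a residue is considered intrinsically disordered
#: (0-100 scale). A single shared constant so every module agrees on the
#: definition of "disordered".
PLDDT_DISORDER_CUTOFF: float = 50.0


def spawn_rng(master_seed: int, *stream: int) -> np.random.Generator:
    """Derive an independent :class:`numpy.random.Generator` from a master seed.

    Each distinct ``stream`` tuple yields a statistically independent stream,
    so no two stages of a run ever share a raw generator.
    """
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, stream)]))


def derive_int_seed(master_seed: int, *stream: int) -> int:
    """A 31-bit integer seed derived deterministically from a master seed.

    Suitable for APIs (scikit-learn ``random_state``) that take plain ints.
    """
    ss = np.random.SeedSequence([int(master_seed), *map(int, stream)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def softplus(x):
    """Numerically stable ``log(1 + exp(x))``."""
    x = np.asarray(x, dtype=float)
    return np.logaddexp(0.0, x)


def inv_softplus(y: float) -> float:
    """Inverse of :func:`softplus` for positive ``y``."""
    return float(np.log(np.expm1(y)))
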