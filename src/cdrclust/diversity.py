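"""Back-of-envelope estimate of the naive antibody repertoire size.

Combinatorics of V(D)J recombination: the germline carries roughly 40
functional variable (V) genes of each type (heavy, kappa, lambda), 5
functional joining (J) genes of each type and 23 functional diversity (D)
genes (heavy chain only).  Junctional N-diversity and somatic hypermutation
multiply the number of realizable sequences per chain by about a
thousand-fold.  Pairing any heavy chain with any light chain then gives an
estimate of the number of distinct antibodies a human can produce.
"""

from __future__ import annotations

__all__ = ["estimate_antibody_diversity"]


def estimate_antibody_diversity(
    n_v: int = 40,
    n_j: int = 5,
    n_d: int = 23,
    chain_expansion: float = 1000.0,
) -> dict[str, float]:
    """Estimated number of distinct antibodies from germline gene counts.

    Returns the per-chain counts and the total (heavy x light pairings).
    With the default gene counts the total is ~1.8e12, i.e. about 10^12.
    """
    heavy = n_v * n_d * n_j * chain_expansion
    light = (n_v * n_j + n_v * n_j) * chain_expansion  # kappa + lambda
    return {
        "heavy_chain": heavy,
        "light_chain": light,
        "total": heavy * light,
    }
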