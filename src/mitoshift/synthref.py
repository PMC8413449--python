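"""Deterministic synthetic stand-in for the rCRS base sequence.

The package's bundled reference uses the *real* standard gene/region
coordinates but a *synthetic* 16,569-base sequence: bases are drawn from the
human mtDNA L-strand composition with a fixed internal seed, then a small
set of structural features is pinned so the sequence behaves like the real
molecule where the analysis cares:

* homopolymer / short-repeat runs at the six low-complexity intervals,
* ATG start codons for the thirteen protein genes (on the correct strand),
* reference alleles at the bundled pathogenic sites and at the recurrent
  hotspot positions (m.414T, m.2623A, ...).

Everything downstream treats the sequence as opaque, so swapping in a real
rCRS FASTA changes no interfaces.  This module exists so the repository
ships no sequence data and every run regenerates the same reference.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

MT_LENGTH = 16_569

# L-strand base composition of human mtDNA (approximate published values).
_BASES = np.array(list("ACGT"))
_PROBS = np.array([0.309, 0.313, 0.131, 0.247])

# low-complexity fills: poly-C/poly-A tracts and the CA repeat at 513-525
_LOW_COMPLEXITY_FILL = {
    (66, 71): "CCCCCC",
    (300, 316): "CCCCCCCTCCCCCGCTT",
    (513, 525): "CACACACACACAC",
    (3106, 3107): "CC",
    (12418, 12425): "AAAAAAAA",
    (16182, 16194): "CCCCCCCCCCCCC",
}

# pinned reference alleles: recurrent hotspots and single-cell marker examples
_PINNED = {414: "T", 1392: "T", 2623: "A", 13327: "A", 13369: "T"}

# (start, end, strand) of the 13 protein genes; start codons are pinned to ATG
_PROTEIN_GENES = [
    (3307, 4262, "H"), (4470, 5511, "H"), (5904, 7445, "H"), (7586, 8269, "H"),
    (8366, 8572, "H"), (8527, 9207, "H"), (9207, 9990, "H"), (10059, 10404, "H"),
    (10470, 10766, "H"), (10760, 12137, "H"), (12337, 14148, "H"),
    (14149, 14673, "L"), (14747, 15887, "H"),
]

_INTERNAL_SEED = 20_210_902  # fixed: the bundled reference is a constant


@lru_cache(maxsize=1)
def synthetic_rcrs_sequence() -> str:
    rng = np.random.Generator(np.random.PCG64(_INTERNAL_SEED))
    seq = rng.choice(_BASES, size=MT_LENGTH, p=_PROBS)

    for (a, b), fill in _LOW_COMPLEXITY_FILL.items():
        assert len(fill) == b - a + 1
        seq[a - 1:b] = list(fill)

    for start, end, strand in _PROTEIN_GENES:
        if strand == "H":
            seq[start - 1:start + 2] = list("ATG")
        else:  # sense on the reverse complement: last three bases read CAT
            seq[end - 3:end] = list("CAT")

    for pos, base in _PINNED.items():
        seq[pos - 1] = base

    # pathogenic-site reference alleles from the bundled table
    from importlib import resources

    import pandas as pd

    table = pd.read_csv(
        resources.files("mitoshift").joinpath("data", "pathogenic_sites.tsv"),
        sep="\t",
    )
    for _, row in table.iterrows():
        seq[int(row["position"]) - 1] = str(row["ref"])

    return "".join(seq)
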