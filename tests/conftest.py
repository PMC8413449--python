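import pandas as pd
import pytest

from mitoshift import default_reference


@pytest.fixture(scope="session")
def ref():
    return default_reference()


def make_call(sample_id="S1", position=3000, ref_base=None, alt=None,
              allele_fraction=0.10, depth=1000, alt_forward=None,
              alt_reverse=None, source="wgs_bulk", reference=None):
    """One well-formed variant-call row; alleles default to the reference base
    and a transition, strand counts to an even split of the alt reads."""
    if reference is not None and ref_base is None:
        ref_base = reference.base(position)
    ref_base = ref_base or "A"
    if alt is None:
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
    n_alt = int(round(allele_fraction * depth))
    if alt_forward is None:
        alt_forward = n_alt // 2
    if alt_reverse is None:
        alt_reverse = n_alt - n_alt // 2
    return {"sample_id": sample_id, "position": position, "ref": ref_base,
            "alt": alt, "allele_fraction": allele_fraction, "depth": depth,
            "alt_forward": alt_forward, "alt_reverse": alt_reverse,
            "source": source}


def calls_frame(rows):
    return pd.DataFrame(rows)
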