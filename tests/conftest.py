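import pytest

from summarymr.types import VariantAssociation


@pytest.fixture
def make_record():
    """Factory for valid association records with overridable fields."""

    def _make(snp_id="rs1", **kwargs):
        defaults = dict(
            snp_id=snp_id,
            effect_allele="A",
            other_allele="G",
            eaf=0.3,
            beta=0.1,
            se=0.01,
            pvalue=1e-10,
            n=100_000.0,
        )
        defaults.update(kwargs)
        return VariantAssociation(**defaults)

    return _make
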