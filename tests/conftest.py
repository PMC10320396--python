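import numpy as np
import pandas as pd
import pytest

from xwaskit.io_formats import GenotypePanel, GwasTable, ProbeInfo, SnpAssoc


def make_snp(snp_id="rs1", a1="A", a2="G", freq=0.3, beta=0.1, se=0.02,
             p=1e-8, chrom="1", pos=1000, n=None):
    return SnpAssoc(snp_id=snp_id, a1=a1, a2=a2, freq=freq, beta=beta,
                    se=se, p=p, chrom=chrom, pos=pos, n=n)


@pytest.fixture
def simple_panel():
    """4 individuals x 3 SNPs; columns 1 and 2 identical, column 3 varies."""
    dosages = np.array(
        [[0.0, 0.0, 2.0], [1.0, 1.0, 1.0], [2.0, 2.0, 0.0], [1.0, 1.0, 2.0]]
    )
    meta = pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3"],
            "chrom": ["1", "1", "1"],
            "pos": [1000, 2000, 3000],
            "a1": ["A", "C", "G"],
            "a2": ["G", "T", "A"],
        }
    )
    return GenotypePanel(dosages=dosages, meta=meta)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """A small but complete simulated input bundle, run end to end once."""
    from xwaskit import pipeline
    from xwaskit.synthetic_data import FixtureSpec, write_fixture_set

    root = tmp_path_factory.mktemp("bundle")
    fx = FixtureSpec(n_causal=60, n_linkage=30, n_null=30, m_snps=20, n_ref=400)
    truth = write_fixture_set(root, master_seed=7, fx=fx)
    result = pipeline.run_bundle(root)
    return {"dir": root, "truth": truth, "result": result, "fx": fx}
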