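import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=200, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def tiny_gtf(tmp_path):
    """Three genes in ensembl GTF dialect (1-based closed coordinates)."""
    text = (
        'chr1\ttest\tgene\t10001\t15000\t.\t+\t.\tgene_id "GA"; gene_name "GA";\n'
        'chr1\ttest\texon\t10001\t10500\t.\t+\t.\tgene_id "GA";\n'
        'chr1\ttest\tgene\t30001\t36000\t.\t-\t.\tgene_id "GB";\n'
        'chr2\ttest\tgene\t501\t3000\t.\t+\t.\tgene_id "GC";\n'
    )
    path = tmp_path / "genes.gtf"
    path.write_text(text)
    return path


@pytest.fixture
def tiny_bed(tmp_path):
    text = "chr1\t10000\t15000\tGA\t0\t+\nchr1\t30000\t36000\tGB\t0\t-\nchr2\t500\t3000\tGC\t0\t+\n"
    path = tmp_path / "genes.bed"
    path.write_text(text)
    return path
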