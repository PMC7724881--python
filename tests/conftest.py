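import pytest

from litfdr import PanelConfig, generate_corpus, generate_journal_panel
from litfdr.synthetic import EXACT_ONLY


@pytest.fixture(scope="session")
def small_panel():
    """3 oncology + 2 medicine journals, 5 years, default effect sizes."""
    cfg = PanelConfig(n_oncology=3, n_medicine=2, seed=11)
    return generate_journal_panel(cfg)


@pytest.fixture(scope="session")
def exact_corpus(tmp_path_factory, small_panel):
    """MEDLINE corpus with exact-only reporting plus its ground truth."""
    meta, truth, _ = small_panel
    path = tmp_path_factory.mktemp("corpus") / "exact.medline"
    gt = generate_corpus(meta, truth, str(path), policy=EXACT_ONLY,
                         pvalues_per_cell=40, seed=21)
    return str(path), gt


@pytest.fixture(scope="session")
def mixed_corpus(tmp_path_factory, small_panel):
    """MEDLINE corpus with the default exact/rounded/truncated mix."""
    meta, truth, _ = small_panel
    path = tmp_path_factory.mktemp("corpus") / "mixed.medline"
    gt = generate_corpus(meta, truth, str(path), pvalues_per_cell=40, seed=22)
    return str(path), gt
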