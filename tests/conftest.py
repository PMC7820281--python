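import numpy as np
import pandas as pd
import pytest

from mvpscore import synth
from mvpscore import variants as vt


@pytest.fixture
def tiny_table(tmp_path):
    """A 3-variant TSV with two feature columns, one cell unparseable."""
    path = tmp_path / "variants.tsv"
    path.write_text(
        "chrom\tpos\tref\talt\tgene\tpli\tmaf\tlabel\tcons_a\tcomplex_b\n"
        "1\t100\tA\tG\tG1\t0.9\t5e-05\tpathogenic\t1.5\t0.2\n"
        "2\t200\tC\tT\tG2\t0.1\t0.0\tbenign\tNA\t0.7\n"
        "3\t300\tG\tA\tG3\t0.6\t2e-07\tunknown\t-0.3\tNA\n"
    )
    groups = {"cons_a": "conservation", "complex_b": "protein_complex"}
    return path, groups


@pytest.fixture(scope="session")
def small_study():
    """A filled, ordered synthetic feature table shared across model tests."""
    from mvpscore import features as feat

    spec = synth.GeneratorSpec(n_variants=1500, seed=101)
    variants, fm, y, genes = synth.gen_feature_table(spec)
    fm = vt.fill_missing(fm)
    order = feat.fit_feature_order(fm)
    return variants, order.apply(fm), y, genes, order


def brute_force_auc(labels, scores):
    """Pairwise-concordance oracle: P(s_pos > s_neg) + 0.5 P(equal)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
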