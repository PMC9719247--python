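import numpy as np
import pandas as pd
import pytest

import cfpromoter as cf


@pytest.fixture(scope="session")
def small_cohort():
    """15 vs 15 fragment-level cohort with strong promoter depletion."""
    truth = cf.generate_cohort_truth(15, 15, n_genes=80, frac_diff=0.1, fc=2.0, seed=11)
    ann = cf.generate_annotation(80, 500_000, seed=11)
    model = cf.NucleosomeModel(ndr_depth=0.9)
    fsets = cf.simulate_fragments(truth, ann, model, mean_depth=0.3, chrom_length=500_000, seed=11)
    return truth, ann, fsets


@pytest.fixture()
def tiny_annotation():
    return pd.DataFrame(
        {
            "transcript_id": ["t1", "t2", "t3"],
            "gene_id": ["gA", "gA", "gB"],
            "chrom": ["chrS"] * 3,
            "strand": ["+", "-", "+"],
            "tss": [2000, 8000, 14000],
        }
    )


def brute_force_window_coverage(fragments: cf.FragmentSet, annotation, halfwidth=1000):
    """Oracle: per-base weighted depth summed over every base of every window."""
    out = {}
    rec = fragments.records
    for row in annotation.itertuples(index=False):
        on_chrom = rec[rec["chrom"] == row.chrom]
        starts = on_chrom["start"].to_numpy()
        ends = on_chrom["end"].to_numpy()
        weights = on_chrom["weight"].to_numpy()
        total = 0.0
        for base in range(row.tss - halfwidth, row.tss + halfwidth):
            total += float(weights[(starts <= base) & (base < ends)].sum())
        out[row.transcript_id] = total
    return pd.Series(out)


def brute_force_auc(scores, y):
    """Oracle: explicit all-pairs concordance with ties counting one half."""
    scores = np.asarray(scores, float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
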