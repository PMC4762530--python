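import numpy as np
import pandas as pd
import pytest

from tdbu.types import StudyDesign


@pytest.fixture
def study3():
    return StudyDesign.study3()


@pytest.fixture
def study2():
    return StudyDesign.study2()


def bu_table(rows):
    """Build a BU count table from (peptide, accession, unique, variant,
    state, gelfree, lcms, count) tuples."""
    return pd.DataFrame(
        rows,
        columns=["peptide_seq", "protein_accession", "unique_flag",
                 "variant_kind", "state", "gelfree_rep", "lcms_rep",
                 "spectral_count"],
    )


def replicate_count_table(accession, totals_by_state_rep):
    """One peptide per protein, one run per GELFrEE replicate, carrying the
    replicate total directly."""
    rows = []
    for (state, rep), total in totals_by_state_rep.items():
        if total > 0:
            rows.append((f"{accession}:pep", accession, True, "none",
                         state, rep, 1, total))
    return bu_table(rows)


def bh_step_up_brute_force(p, alpha):
    """Textbook BH: scan all ranks for the largest i with p(i) <= i*alpha/m;
    q-values as the monotone minimum of p(j)*m/j over j >= i."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    k = 0
    for i in range(1, m + 1):
        if ps[i - 1] <= i * alpha / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    q_sorted = np.minimum.accumulate(
        (ps * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q, reject
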