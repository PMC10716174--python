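import numpy as np
import pandas as pd
import pytest

from nspquant import io
from nspquant.simulate import SimDesign, generate_ground_truth, simulate_precursor_report

MIX1 = {"L": 0.70, "M": 0.15, "H": 0.15}
MIX2 = {"L": 0.20, "M": 0.40, "H": 0.40}


@pytest.fixture
def mix1_design():
    return SimDesign(n_proteins=60, channel_proportions=dict(MIX1), seed=101)


@pytest.fixture
def mix2_design():
    return SimDesign(n_proteins=60, channel_proportions=dict(MIX2), seed=102)


@pytest.fixture
def noiseless_mix1_design():
    return SimDesign(
        n_proteins=40,
        channel_proportions=dict(MIX1),
        noise_sd_log2=0.0,
        missing_rate=0.0,
        decoy_rate=0.0,
        seed=103,
    )


@pytest.fixture
def small_filtered_table(mix2_design, tmp_path):
    """A small synthetic table run through the standard filters."""
    truth = generate_ground_truth(mix2_design)
    report = simulate_precursor_report(truth, mix2_design)
    path = tmp_path / "report.tsv"
    report.to_csv(path, sep="\t", index=False)
    table = io.read_precursor_table(path)
    cfg = io.FilterConfig()
    return io.apply_qvalue_filters(io.remove_contaminants(table, cfg), cfg)


def make_precursor_frame(rows):
    """Build a canonical precursor DataFrame from dict rows, filling
    sensible defaults for omitted columns."""
    defaults = {
        "protein_group": "P1",
        "gene": "G1",
        "stripped_sequence": "AAAK",
        "modified_sequence": "AAAK",
        "charge": 2,
        "channel": "H",
        "run": "r1",
        "ms1_quantity": 100.0,
        "ms2_quantity": 100.0,
        "q_value": 0.001,
        "channel_q_value": 0.001,
        "translated_q_value": 0.001,
    }
    frame = pd.DataFrame([{**defaults, **r} for r in rows])
    frame.attrs["quant_source"] = "MS2"
    return frame


def brute_force_maxlfq(matrix, min_shared=1):
    """Independent least-squares oracle for MaxLFQ.

    Stacks one equation x_b - x_a = median(log2 I_b - log2 I_a) per
    column pair sharing >= min_shared precursors and solves the
    overdetermined system with numpy lstsq, then anchors each connected
    component so its summed linear abundance equals the component's
    total observed intensity.  Shares no code with the implementation.
    """
    X = np.asarray(matrix, float)
    X = np.where(X > 0, X, np.nan)
    L = np.log2(X)
    p, c = L.shape
    present = np.isfinite(L)
    observed = present.any(axis=0)

    pairs, rhs = [], []
    for a in range(c):
        for b in range(a + 1, c):
            both = present[:, a] & present[:, b]
            if both.sum() >= min_shared:
                pairs.append((a, b))
                rhs.append(np.median(L[both, b] - L[both, a]))

    # connected components by naive label propagation
    labels = list(range(c))
    changed = True
    while changed:
        changed = False
        for a, b in pairs:
            m = min(labels[a], labels[b])
            for i in (a, b):
                if labels[i] != m:
                    labels[i] = m
                    changed = True

    out = np.full(c, np.nan)
    col_sums = np.nansum(X, axis=0)
    for lab in set(labels):
        cols = [i for i in range(c) if labels[i] == lab and observed[i]]
        if not cols:
            continue
        if len(cols) == 1:
            out[cols[0]] = col_sums[cols[0]]
            continue
        sub_pairs = [(a, b, r) for (a, b), r in zip(pairs, rhs) if a in cols]
        A = np.zeros((len(sub_pairs), len(cols)))
        y = np.zeros(len(sub_pairs))
        pos = {ci: j for j, ci in enumerate(cols)}
        for i, (a, b, r) in enumerate(sub_pairs):
            A[i, pos[a]] = -1.0
            A[i, pos[b]] = 1.0
            y[i] = r
        x = np.linalg.lstsq(A, y, rcond=None)[0]
        total = col_sums[cols].sum()
        x = x + np.log2(total / np.sum(2.0**x))
        for ci, j in pos.items():
            out[ci] = 2.0 ** x[j]
    return out


def random_peptide_matrix(rng, max_prec=8, max_cols=6):
    """Random small intensity matrix with missingness, guaranteed to
    have at least one observed value."""
    while True:
        p = rng.integers(1, max_prec + 1)
        c = rng.integers(2, max_cols + 1)
        X = 2.0 ** rng.normal(14, 2, size=(p, c))
        X[rng.random((p, c)) < 0.3] = np.nan
        if np.isfinite(X).any():
            return X
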