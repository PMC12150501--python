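"""Self-contained brute-force oracles used by the reproduction script."""

import numpy as np
import pandas as pd
from scipy import stats

from pgsem.sumstats import SumStats


def greedy_clump_oracle(pvals, positions, R, window_bp, r2_max):
    """Naive re-implementation of greedy LD clumping (single chromosome)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: (pvals[i], positions[i]))
    claimed = [False] * m
    picked = []
    for i in order:
        if claimed[i]:
            continue
        picked.append(i)
        claimed[i] = True
        for j in range(m):
            if claimed[j]:
                continue
            if abs(positions[j] - positions[i]) <= window_bp and R[i, j] ** 2 > r2_max:
                claimed[j] = True
    return picked


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def toy_sumstats(panel, pvals) -> SumStats:
    """Minimal valid sumstats table on a panel's SNP grid."""
    m = panel.m
    rng = np.random.default_rng(0)
    beta = rng.normal(0, 0.05, m)
    se = np.full(m, 0.02)
    table = pd.DataFrame({
        "SNP": panel.snp_ids, "CHR": panel.chrom, "BP": panel.positions,
        "A1": "A", "A2": "G", "BETA": beta, "SE": se,
        "P": np.asarray(pvals, float),
        "N": 10000, "MAF": panel.maf,
    })
    return SumStats(table, trait="oracle")
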