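"""Shared fixtures: small synthetic bundles and hand-built matrices."""

from __future__ import annotations

import numpy as np
import pytest

from lpsmotif.io import ExpressionMatrix, ExpressionRecord
from lpsmotif.simulate import SyntheticConfig, generate_bundle


def make_record(probe_id, symbol, n, nl, tl, t=None) -> ExpressionRecord:
    values = {"N": np.asarray(n, float), "NL": np.asarray(nl, float),
              "TL": np.asarray(tl, float)}
    if t is not None:
        values["T"] = np.asarray(t, float)
    return ExpressionRecord(probe_id, symbol, values)


def make_matrix(rows, n_reps=2) -> ExpressionMatrix:
    """rows: iterable of (probe_id, symbol, n, nl, tl[, t]) replicate tuples."""
    records = [make_record(*r) for r in rows]
    design = {c: len(records[0].values[c]) for c in records[0].values}
    return ExpressionMatrix(records, design)


@pytest.fixture()
def record_builder():
    return make_record


@pytest.fixture()
def matrix_builder():
    return make_matrix


@pytest.fixture(scope="session")
def small_bundle():
    """A compact bundle: 150 genes, 20% pro, short promoters, 4 decoys."""
    cfg = SyntheticConfig(
        n_genes=150, frac_pro=0.20, frac_anti=0.04,
        promoter_length=400, n_decoys=4, n_curated_targets=10, seed=11,
    )
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def four_condition_bundle():
    cfg = SyntheticConfig(
        n_genes=120, frac_pro=0.25, frac_anti=0.05,
        promoter_length=300, n_decoys=3, include_tolerant_condition=True, seed=17,
    )
    return generate_bundle(cfg)


#: A TRANSFAC-style library text. The M00062/IRF-1 block is a synthetic
#: stand-in with IRF-like TTTC-repeat counts, not the database matrix.
MINI_TRANSFAC = """\
AC  M00062
XX
ID  V$IRF1_SYN
XX
NA  IRF-1
XX
P0      A      C      G      T
01      2      1      1     16
02      1      0      1     18
03      1      1      0     18
04      0     19      0      1
05     12      2      4      2
06      3      5      6      6
07      2      1      1     16
08      1      1      1     17
09      0     18      1      1
10     13      2      3      2
XX
//
AC  M00971
XX
NA  Ets-1
XX
P0      A      C      G      T
01      0.10   0.20   0.60   0.10
02      0.05   0.05   0.85   0.05
03      0.80   0.05   0.10   0.05
04      0.70   0.10   0.10   0.10
05      0.05   0.05   0.85   0.05
06      0.10   0.10   0.10   0.70
XX
//
"""
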