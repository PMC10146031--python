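"""Shared fixtures.

The expensive session fixtures run the synthetic four-category benchmark at
reduced problem sizes (sub-region 200 bp, flanks 100 bp, 300 reads/sample)
so the whole suite stays within a normal CI budget; the category window
offsets - the actual study conditions - are the same as at full size.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from isc.pipeline import correct_bundle, evaluate_pairs, window_length
from isc.synth import make_category_bundle

SEED = 7

BUNDLE_KW = dict(
    n_samples_per_group=20,
    depth=300,
    region_len=200,
    flank_len=100,
    n_taxa=48,
    n_lineages=16,
)

ANCHORED_PAIRS = [("Long", "Same"), ("Same", "Near"), ("Same", "Short")]


@pytest.fixture(scope="session")
def category_run():
    """Full benchmark: bundle -> correction -> anchored pair evaluations."""
    bundle = make_category_bundle(seed=SEED, **BUNDLE_KW)
    model, corrected, report = correct_bundle(bundle)
    results = evaluate_pairs(bundle, corrected, seed=SEED,
                             pairs=ANCHORED_PAIRS)
    lengths = {g: window_length(bundle, g) for g in bundle.samples}
    return dict(bundle=bundle, model=model, corrected=corrected,
                report=report, results=results, lengths=lengths)


@pytest.fixture(scope="session")
def clean_run():
    """Error-free, smaller bundle for sensitivity/coordinate checks."""
    kw = dict(BUNDLE_KW, n_samples_per_group=4, depth=200, error_rate=0.0)
    bundle = make_category_bundle(seed=SEED, **kw)
    model, corrected, report = correct_bundle(bundle)
    return dict(bundle=bundle, model=model, corrected=corrected,
                report=report)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230406)
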