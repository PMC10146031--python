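"""Convenience orchestration: correct a synthetic category bundle and run
the pairwise convergence evaluation, mirroring the per-stage CLI commands.
"""

from __future__ import annotations

from itertools import combinations

from isc.asv import build_table
from isc.extract import IscReport, run_isc
from isc.phmm import ProfileHMM, build_profile
from isc.stats import PairEvaluation, evaluate_pair
from isc.synth import CategoryBundle


def correct_bundle(bundle: CategoryBundle, model: ProfileHMM | None = None,
                   min_bits: float = 20.0, min_coverage: float = 0.5):
    """Train (or reuse) the sub-region model and apply the correction to
    every sample of the bundle.  Returns (model, corrected, report)."""
    if model is None:
        model = build_profile(bundle.msa)
    flat = {
        sid: reads
        for group in bundle.samples.values()
        for sid, reads in group.items()
    }
    corrected, report = run_isc(flat, model, min_bits, min_coverage)
    return model, corrected, report


def window_length(bundle: CategoryBundle, group: str) -> int:
    ds, de = bundle.windows[group]
    return bundle.region_len - ds + de


def evaluate_pairs(bundle: CategoryBundle, corrected: dict,
                   seed: int = 0,
                   permutations: int = 999,
                   pairs: list[tuple[str, str]] | None = None,
                   ) -> dict[tuple[str, str], PairEvaluation]:
    """Evaluate every (or the given) group pair, pre vs post correction.

    Each pair's tables are built independently (reads of both groups pooled
    for denoising, mapped per sample), matching how two datasets would be
    integrated in practice.  Pair keys are ordered with the longer-window
    group first, so Ebar(g1, g2) < 0 means the longer dataset converged
    more.
    """
    if pairs is None:
        names = sorted(bundle.samples,
                       key=lambda g: -window_length(bundle, g))
        pairs = list(combinations(names, 2))
    results: dict[tuple[str, str], PairEvaluation] = {}
    for pi, (g1, g2) in enumerate(pairs):
        sids = list(bundle.samples[g1]) + list(bundle.samples[g2])
        groups = {sid: (g1 if sid in bundle.samples[g1] else g2)
                  for sid in sids}
        raw = {**bundle.samples[g1], **bundle.samples[g2]}
        pre = build_table({sid: raw[sid] for sid in sids},
                          labels={sid: "pre" for sid in sids})
        post = build_table({sid: corrected[sid] for sid in sids},
                           labels={sid: "post" for sid in sids})
        results[(g1, g2)] = evaluate_pair(
            pre, post, groups,
            permutations=permutations, seed=seed + 17 * pi,
        )
    return results
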