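"""Reliability studies on simulated clones.

These are the package's own validation experiments: round-trip recovery,
calibration of the total probable error against observed mismatches,
the subsample-size trend, and the uniform-prior ablation. They are run by
the test suite and by ``scripts/acceptance.py``; sizes are deliberately
modest (toy library, tens of clones) so a study completes in minutes on one
CPU.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .config import RunConfig
from .germline import LibrarySet
from .inference import infer_ua
from .simulate import (
    SimulationTruth,
    recovery_report,
    simulate_rearrangement,
    simulate_shm_clone,
)
from .toylib import toy_heavy_library


def study_config(**overrides) -> RunConfig:
    """Scaled-down inference settings used across the simulation studies:
    an 8-point mu grid spanning the plausible clonal range."""
    kwargs = dict(chain="heavy", mu_lo=0.005, mu_hi=0.3, mu_k=8, max_iter=6)
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def simulate_and_infer(
    seed: int,
    n_leaves: int,
    mu_true: float,
    library: Optional[LibrarySet] = None,
    config: Optional[RunConfig] = None,
) -> tuple[SimulationTruth, dict]:
    library = library or toy_heavy_library()
    config = config or study_config()
    truth = simulate_rearrangement(library, config.prior_config(), seed=seed)
    clone = simulate_shm_clone(
        truth, n_leaves, mu_true, config.cdr3_multiplier, seed=seed
    )
    result = infer_ua(clone.sequences, library, config)
    return clone, recovery_report(clone, result)


def calibration_study(
    seed: int, n_clones: int = 20, n_leaves: int = 10, mu_true: float = 0.05
) -> dict:
    """Segment recovery and probable-error calibration across clones.

    Returns per-role recovery rates and the paired comparison between
    observed modal-UA mismatches and the estimated total probable error
    (whose mean should agree within sampling noise if the posterior is
    calibrated).
    """
    reports = [
        simulate_and_infer(s, n_leaves, mu_true)[1]
        for s in _seeds(seed, n_clones)
    ]
    mism = np.array([r["ua_mismatches"] for r in reports], dtype=float)
    tpe = np.array([r["total_probable_error"] for r in reports])
    diff = mism - tpe
    n = len(diff)
    se_diff = float(diff.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    se_mism = float(mism.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    recovery = {
        role: float(np.mean([r["segment_correct"][role] for r in reports]))
        for role in reports[0]["segment_correct"]
    }
    return {
        "n_clones": n_clones,
        "mean_mismatches": float(mism.mean()),
        "mean_total_probable_error": float(tpe.mean()),
        "mean_difference": float(diff.mean()),
        "se_difference": se_diff,
        "se_mismatches": se_mism,
        "recovery": recovery,
        "reports": reports,
    }


def identifiable(truth: SimulationTruth, min_d: int = 6) -> bool:
    """True when the clone's segments are recoverable in principle: the
    retained D fragment must be long enough to be unique in the library
    (a 1-3 nt remnant is ambiguous for any method)."""
    p = truth.params
    if p.d_id is None:
        return True
    d_len = len(truth.library.d.get(p.d_id).sequence)
    retained = d_len - max(p.r_d1, 0) - max(p.r_d2, 0)
    return retained >= min_d


def roundtrip_study(seed: int, n_clones: int = 5, n_leaves: int = 5) -> dict:
    """Zero-mutation round trip: the modal UA must reproduce the truth.

    Restricted to identifiable clones (see :func:`identifiable`); segment
    posteriors are only expected to concentrate when the data determine the
    segment at all.
    """
    exact, seg_ok, min_post = 0, 0, 1.0
    library = toy_heavy_library()
    config = study_config(mu_lo=0.001, mu_hi=0.1)
    picked: list[SimulationTruth] = []
    for s in _seeds(seed, 50 * n_clones):
        truth = simulate_rearrangement(library, config.prior_config(), seed=s)
        if identifiable(truth):
            picked.append(truth)
        if len(picked) == n_clones:
            break
    for truth in picked:
        s = truth.seed
        clone = simulate_shm_clone(truth, n_leaves, 0.0, seed=s)
        result = infer_ua(clone.sequences, library, config)
        rep = recovery_report(clone, result)
        exact += rep["ua_mismatches"] == 0
        ok = all(rep["segment_correct"].values())
        seg_ok += ok
        if ok:
            for role, key in (("V", "v"), ("D", "d"), ("J", "j")):
                sid = result.junction_summary[key]["segment_id"]
                min_post = min(min_post, result.segment_posteriors[role][sid])
    return {
        "n_clones": n_clones,
        "exact_ua_fraction": exact / n_clones,
        "segment_correct_fraction": seg_ok / n_clones,
        "min_correct_segment_posterior": min_post,
    }


def subsample_trend_study(
    seed: int,
    sizes: tuple[int, ...] = (1, 3, 9),
    n_clones: int = 10,
    n_leaves: int = 27,
    mu_true: float = 0.05,
) -> dict:
    """Mean total probable error per subsample size (expected non-increasing)."""
    library = toy_heavy_library()
    config = study_config()
    rng_seeds = _seeds(seed, n_clones)
    per_size: dict[int, list[float]] = {k: [] for k in sizes}
    for s in rng_seeds:
        truth = simulate_rearrangement(library, config.prior_config(), seed=s)
        clone = simulate_shm_clone(truth, n_leaves, mu_true, seed=s)
        ids = sorted(clone.sequences)
        rng = np.random.default_rng(s)
        for k in sizes:
            chosen = rng.choice(ids, size=k, replace=False)
            subset = {q: clone.sequences[q] for q in chosen}
            result = infer_ua(subset, library, config)
            per_size[k].append(result.total_probable_error)
    means = {k: float(np.mean(v)) for k, v in per_size.items()}
    return {
        "sizes": list(sizes),
        "mean_total_probable_error": means,
        "non_increasing": all(
            means[a] >= means[b] for a, b in zip(sizes, sizes[1:])
        ),
    }


def prior_ablation_study(
    seed: int, n_clones: int = 20, n_leaves: int = 10, mu_true: float = 0.05
) -> dict:
    """Full rearrangement prior vs flat per-position prior.

    The flat model ignores the rearrangement mechanism; its total probable
    error should exceed the full model's on nearly every clone.
    """
    library = toy_heavy_library()
    full_cfg = study_config()
    flat_cfg = study_config(flat_prior=True)
    wins, pairs = 0, []
    for s in _seeds(seed, n_clones):
        truth = simulate_rearrangement(library, full_cfg.prior_config(), seed=s)
        clone = simulate_shm_clone(truth, n_leaves, mu_true, seed=s)
        full = infer_ua(clone.sequences, library, full_cfg)
        # same sequences, same clonal tree: only the prior changes
        flat = infer_ua(
            clone.sequences, library, flat_cfg, initial_tree=full.final_tree
        )
        pairs.append((full.total_probable_error, flat.total_probable_error))
        wins += flat.total_probable_error > full.total_probable_error
    return {
        "n_clones": n_clones,
        "flat_larger_fraction": wins / n_clones,
        "mean_full": float(np.mean([p[0] for p in pairs])),
        "mean_flat": float(np.mean([p[1] for p in pairs])),
    }
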