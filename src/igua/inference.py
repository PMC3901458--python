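"""Posterior inference of the unmutated ancestor (UA).

Combines the rearrangement prior with the tree likelihood: for each value of
the discretized mutation rate mu, every (segment, trim) pair contributes its
maximum-score alignment; hypotheses are the consistent cross-products of
these per-role candidates, with intervening columns attributed to N
nucleotides. Bayes' theorem over hypotheses gives segment posteriors and a
per-column posterior over the ancestral nucleotide; marginalizing over mu
and iterating with clonal-tree re-estimation yields the final result.

The probable error at a position is one minus the maximum posterior there;
its sum over positions estimates the expected number of mismatches between
the modal UA and the true UA.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .config import RunConfig
from .germline import LibrarySet, Role
from .junction import (
    ScoreScheme,
    SegmentAlignment,
    align_role,
    build_score_scheme,
    junction_consistency,
)
from .msa import GAP_CODE, QueryAlignment, align_queries, encode
from .phylo import (
    AncestorProfile,
    CladeTree,
    MuGrid,
    estimate_tree,
    palm_tree,
    root_log_profile,
    unit_normalize,
)
from .rearrangement import PriorConfig, _range_size


class InferenceError(RuntimeError):
    """Raised when no feasible rearrangement hypothesis exists."""


@dataclass
class Hypothesis:
    """One surviving rearrangement hypothesis with its posterior weight."""

    v: SegmentAlignment
    j: SegmentAlignment
    d: Optional[SegmentAlignment]
    log_score: float
    weight: float = 0.0


@dataclass
class MuStratum:
    """Per-mu working set: profile, scheme, surviving hypotheses."""

    mu: float
    log_profile: np.ndarray
    scheme: ScoreScheme
    hypotheses: list[Hypothesis]
    evidence: float


@dataclass
class HypothesisPosterior:
    """Posterior over rearrangement hypotheses, stratified by mu."""

    strata: list[MuStratum]
    mu_grid: MuGrid
    segment_posteriors: dict[str, dict[str, float]]
    library: LibrarySet


def candidate_log_prior(
    library: LibrarySet, seg_aln: SegmentAlignment, pconf: PriorConfig
) -> float:
    """Allele prior times uniform trim prior(s) for one candidate."""
    lib = library.library(seg_aln.role)
    seg = lib.get(seg_aln.segment_id)
    lp = math.log(lib.allele_prior[seg_aln.segment_id])
    if seg_aln.role is Role.D:
        lp -= 2.0 * math.log(_range_size(seg, pconf))
    else:
        lp -= math.log(_range_size(seg))
    return lp


def factorized_log_likelihood(
    v_aln: SegmentAlignment,
    j_aln: SegmentAlignment,
    scheme: ScoreScheme,
    library: LibrarySet,
    config: PriorConfig,
    d_aln: Optional[SegmentAlignment] = None,
) -> float:
    """Log posterior score of one hypothesis (likelihood x prior, unnormalized).

    Equals sum_i N_i plus each segment's N-adjusted alignment score plus the
    segment and trim priors; -inf when the placements overlap or an implied
    N region exceeds n_max.
    """
    d_interval = (d_aln.start_col, d_aln.end_col) if d_aln is not None else None
    if not junction_consistency(v_aln.end_col, j_aln.start_col, d_interval):
        return -math.inf
    if d_aln is None:
        n_lengths = [j_aln.start_col - v_aln.end_col - 1]
    else:
        n_lengths = [
            d_aln.start_col - v_aln.end_col - 1,
            j_aln.start_col - d_aln.end_col - 1,
        ]
    if any(n < 0 or n > config.n_max for n in n_lengths):
        return -math.inf
    total = scheme.n_total
    for aln in (v_aln, j_aln) + ((d_aln,) if d_aln is not None else ()):
        total += aln.score + candidate_log_prior(library, aln, config)
    return total


def _role_candidates(
    library: LibrarySet, role: Role, scheme: ScoreScheme, pconf: PriorConfig
) -> list[SegmentAlignment]:
    return align_role(list(library.library(role)), scheme, pconf)


def posterior_over_hypotheses(
    alignment: QueryAlignment,
    library: LibrarySet,
    tree: CladeTree,
    mu_grid: MuGrid,
    config: RunConfig,
    cdr3_mask: Optional[np.ndarray] = None,
) -> HypothesisPosterior:
    """Enumerate and weight rearrangement hypotheses on each mu grid point."""
    pconf = config.prior_config()
    heavy = library.d is not None
    strata: list[MuStratum] = []
    evidences = np.empty(len(mu_grid.values))

    for gi, mu in enumerate(mu_grid.values):
        prof = root_log_profile(
            alignment, tree, float(mu), cdr3_mask, config.cdr3_multiplier
        )
        scheme = build_score_scheme(
            AncestorProfile(prof, "log_likelihood"),
            gap_penalty=config.gap_penalty,
            free_end_gaps=config.free_end_gaps,
            nongap_counts=(alignment.matrix != GAP_CODE).sum(axis=0),
        )
        v_c = _role_candidates(library, Role.V, scheme, pconf)
        j_c = _role_candidates(library, Role.J, scheme, pconf)
        sv = np.array([c.score + candidate_log_prior(library, c, pconf) for c in v_c])
        sj = np.array([c.score + candidate_log_prior(library, c, pconf) for c in j_c])
        v_end = np.array([c.end_col for c in v_c])
        j_start = np.array([c.start_col for c in j_c])

        if not heavy:
            tot = sv[:, None] + sj[None, :] + scheme.n_total
            nlen = j_start[None, :] - v_end[:, None] - 1
            tot = np.where((nlen >= 0) & (nlen <= pconf.n_max), tot, -np.inf)
        else:
            d_c = _role_candidates(library, Role.D, scheme, pconf)
            sd = np.array(
                [c.score + candidate_log_prior(library, c, pconf) for c in d_c]
            )
            d_start = np.array([c.start_col for c in d_c])
            d_end = np.array([c.end_col for c in d_c])
            tot = (
                sv[:, None, None]
                + sd[None, :, None]
                + sj[None, None, :]
                + scheme.n_total
            )
            n1 = d_start[None, :, None] - v_end[:, None, None] - 1
            n2 = j_start[None, None, :] - d_end[None, :, None] - 1
            ok_d = (d_end >= d_start)[None, :, None]
            valid = (
                (n1 >= 0) & (n1 <= pconf.n_max) & (n2 >= 0) & (n2 <= pconf.n_max) & ok_d
            )
            tot = np.where(valid, tot, -np.inf)

        finite = np.isfinite(tot)
        if not finite.any():
            # placements collide at this rate; the stratum carries no mass
            strata.append(MuStratum(float(mu), prof, scheme, [], -np.inf))
            evidences[gi] = -np.inf
            continue
        evidence = float(logsumexp(tot[finite]))
        best = float(tot[finite].max())
        keep = np.argwhere(tot >= best - config.prune_threshold)
        if keep.shape[0] > config.max_hypotheses:
            vals = tot[tuple(keep.T)]
            order = np.argsort(vals)[::-1][: config.max_hypotheses]
            keep = keep[order]
        kept_scores = tot[tuple(keep.T)]
        w = np.exp(kept_scores - logsumexp(kept_scores))
        hyps = []
        for row, score, weight in zip(keep, kept_scores, w):
            if heavy:
                i, k, m = row
                hyps.append(
                    Hypothesis(v_c[i], j_c[m], d_c[k], float(score), float(weight))
                )
            else:
                i, m = row
                hyps.append(Hypothesis(v_c[i], j_c[m], None, float(score), float(weight)))
        strata.append(MuStratum(float(mu), prof, scheme, hyps, evidence))
        evidences[gi] = evidence

    log_post = np.log(mu_grid.prior) + evidences
    if not np.isfinite(log_post).any():
        raise InferenceError(
            "no consistent rearrangement hypothesis on any mu grid point "
            f"(all V/D/J placements overlap or exceed n_max={pconf.n_max})"
        )
    mu_post = np.exp(log_post - logsumexp(log_post))
    grid = MuGrid(mu_grid.values, mu_grid.prior, mu_post)

    seg_post: dict[str, dict[str, float]] = {}
    roles = [Role.V, Role.D, Role.J] if heavy else [Role.V, Role.J]
    for role in roles:
        acc: dict[str, float] = {}
        for stratum, wmu in zip(strata, mu_post):
            for hyp in stratum.hypotheses:
                aln = {Role.V: hyp.v, Role.D: hyp.d, Role.J: hyp.j}[role]
                acc[aln.segment_id] = acc.get(aln.segment_id, 0.0) + wmu * hyp.weight
        seg_post[role.value] = acc
    return HypothesisPosterior(strata, grid, seg_post, library)


_ONEHOT = np.eye(4)


def _stratum_profile(stratum: MuStratum, pconf: PriorConfig) -> np.ndarray:
    """Posterior (L, 4) over the ancestral base, conditional on this mu.

    Germline-covered columns take the hypothesis's point mass; N columns (and
    rare ancestor-gap columns) take the likelihood-weighted pi_N posterior.
    """
    log_pi = np.log([pconf.pi_n[b] for b in "ACGT"])
    z = stratum.log_profile + log_pi[None, :]
    pn = np.exp(z - logsumexp(z, axis=1, keepdims=True))
    L = pn.shape[0]
    # A hypothesis's column distribution differs from the all-N baseline only
    # on its segment-covered columns, and those columns depend on the segment
    # alignment alone — so the mixture decomposes over candidates, weighted
    # by each candidate's total posterior mass.
    cand_weight: dict[int, float] = {}
    cand_obj: dict[int, SegmentAlignment] = {}
    total_w = 0.0
    for hyp in stratum.hypotheses:
        total_w += hyp.weight
        for aln in (hyp.v, hyp.d, hyp.j):
            if aln is None:
                continue
            cand_weight[id(aln)] = cand_weight.get(id(aln), 0.0) + hyp.weight
            cand_obj[id(aln)] = aln
    prof = total_w * pn
    for key, w in cand_weight.items():
        aln = cand_obj[key]
        for col, code in aln.column_map(stratum.scheme).items():
            if code is not None and 0 <= col < L:
                prof[col] += w * (_ONEHOT[code] - pn[col])
    return prof


def position_posterior(
    hp: HypothesisPosterior, pconf: Optional[PriorConfig] = None
) -> AncestorProfile:
    """Marginal per-column posterior over the ancestral nucleotide."""
    pconf = pconf or PriorConfig()
    profiles = [_stratum_profile(s, pconf) for s in hp.strata]
    evidences = np.array([s.evidence for s in hp.strata])
    profile, _ = marginalize_mu(profiles, evidences, hp.mu_grid)
    return profile


def marginalize_mu(
    per_mu_profiles: Sequence[np.ndarray],
    per_mu_log_evidence: np.ndarray,
    mu_grid: MuGrid,
) -> tuple[AncestorProfile, MuGrid]:
    """Mix per-mu posteriors by the mu posterior (prior x marginal likelihood)."""
    log_post = np.log(mu_grid.prior) + np.asarray(per_mu_log_evidence, dtype=float)
    if not np.isfinite(log_post).any():
        raise InferenceError("all mu grid points have -inf likelihood")
    w = np.exp(log_post - logsumexp(log_post))
    mixed = np.tensordot(w, np.stack(per_mu_profiles), axes=1)
    mixed = np.maximum(mixed, 0.0)
    mixed /= mixed.sum(axis=1, keepdims=True)
    return (
        AncestorProfile(mixed, "posterior"),
        MuGrid(mu_grid.values, mu_grid.prior, w),
    )


def probable_error(profile: AncestorProfile) -> tuple[np.ndarray, float]:
    """Per-position probable error (1 - max posterior) and its sum."""
    if profile.mode != "posterior":
        raise ValueError("probable_error needs a posterior-mode profile")
    vec = 1.0 - profile.values.max(axis=1)
    return vec, float(vec.sum())


def compute_cdr3_mask(
    hyp: Hypothesis,
    library: LibrarySet,
    scheme: ScoreScheme,
    length: int,
) -> Optional[np.ndarray]:
    """CDR3 columns: strictly after the V Cys codon, strictly before the J
    Trp/Phe codon, mapped through the modal segment alignments."""
    v_seg = library.v.get(hyp.v.segment_id)
    j_seg = library.j.get(hyp.j.segment_id)
    if v_seg.anchor is None or j_seg.anchor is None:
        return None
    cys_end_idx = v_seg.anchor + 2  # fragment index == germline index for V
    r_j = hyp.j.trims[0]
    trp_idx = j_seg.anchor - r_j
    try:
        cys_col = hyp.v.fragment_index_column(scheme, cys_end_idx)
        trp_col = hyp.j.fragment_index_column(scheme, trp_idx)
    except (KeyError, IndexError):
        return None
    if cys_col is None or trp_col is None or trp_col <= cys_col + 1:
        return None
    mask = np.zeros(length, dtype=bool)
    mask[cys_col + 1 : trp_col] = True
    return mask


def _flat_posterior(
    alignment: QueryAlignment,
    tree: CladeTree,
    mu_grid: MuGrid,
    config: RunConfig,
) -> tuple[AncestorProfile, MuGrid]:
    """Uniform-prior ablation: independent flat base priors per column,
    no rearrangement model."""
    log_quarter = math.log(0.25)
    profiles, evidences = [], []
    for mu in mu_grid.values:
        prof = root_log_profile(alignment, tree, float(mu), None, config.cdr3_multiplier)
        z = prof + log_quarter
        col_ev = logsumexp(z, axis=1)
        profiles.append(np.exp(z - col_ev[:, None]))
        evidences.append(float(col_ev.sum()))
    return marginalize_mu(profiles, np.array(evidences), mu_grid)


@dataclass
class UAResult:
    """Complete output of the UA inference."""

    modal_ua: str
    position_posterior: AncestorProfile
    probable_error: np.ndarray
    total_probable_error: float
    segment_posteriors: dict[str, dict[str, float]]
    junction_summary: dict
    mu_posterior: MuGrid
    final_tree: CladeTree
    iterations: int
    converged: bool
    mutation_frequency: float
    alignment: QueryAlignment
    cdr3_mask: Optional[np.ndarray] = None


def _modal_hypothesis(hp: HypothesisPosterior) -> tuple[MuStratum, Hypothesis]:
    si = int(np.argmax(hp.mu_grid.posterior))
    stratum = hp.strata[si]
    hyp = max(stratum.hypotheses, key=lambda h: h.weight)
    return stratum, hyp


def _junction_summary(
    hp: HypothesisPosterior, profile: AncestorProfile
) -> tuple[dict, Optional[np.ndarray], MuStratum]:
    stratum, hyp = _modal_hypothesis(hp)
    modal = profile.modal_sequence()

    def seg_entry(aln: SegmentAlignment) -> dict:
        return {
            "segment_id": aln.segment_id,
            "trims": list(aln.trims),
            "columns": [int(aln.start_col), int(aln.end_col)],
        }

    summary = {"v": seg_entry(hyp.v), "j": seg_entry(hyp.j)}
    if hyp.d is not None:
        summary["d"] = seg_entry(hyp.d)
        spans = [
            ("n1", hyp.v.end_col + 1, hyp.d.start_col),
            ("n2", hyp.d.end_col + 1, hyp.j.start_col),
        ]
    else:
        spans = [("n1", hyp.v.end_col + 1, hyp.j.start_col)]
    for name, a, b in spans:
        summary[name] = {"length": int(b - a), "sequence": modal[a:b]}
    return summary, hyp, stratum


def trees_converged(t1: CladeTree, t2: CladeTree, tol: float = 1e-4) -> bool:
    """Same rooted topology and no branch moved more than ``tol``."""
    c1, c2 = t1.clade_lengths(), t2.clade_lengths()
    if set(c1) != set(c2):
        return False
    return max(abs(c1[k] - c2[k]) for k in c1) < tol


def infer_ua(
    queries: Mapping[str, str] | QueryAlignment,
    library: LibrarySet,
    config: Optional[RunConfig] = None,
    initial_tree: Optional[CladeTree] = None,
) -> UAResult:
    """Run the full iterative UA inference.

    Aligns the queries (identity when already column-compatible), initializes
    a palm tree, then alternates posterior computation over rearrangement
    hypotheses (integrating over mu) with clonal-tree re-estimation using the
    modal UA at the root, until the unit tree stabilizes.
    """
    config = config or RunConfig(chain=library.chain)
    if (config.chain == "heavy") != (library.d is not None):
        raise ValueError(f"config chain {config.chain!r} does not match libraries")
    if isinstance(queries, QueryAlignment):
        alignment = queries
    else:
        if not queries:
            raise ValueError("need at least one query sequence")
        cleaned = {k: v.upper().replace("U", "T") for k, v in queries.items()}
        alignment = align_queries(cleaned)
    mu_grid = MuGrid.log_spaced(config.mu_lo, config.mu_hi, config.mu_k)
    pconf = config.prior_config()

    if initial_tree is not None:
        t1, _ = unit_normalize(initial_tree)
        fixed_tree = True
    else:
        t1 = palm_tree(alignment.ids)
        fixed_tree = False

    mask: Optional[np.ndarray] = None
    converged = False
    iterations = 0
    hp: Optional[HypothesisPosterior] = None

    for iterations in range(1, config.max_iter + 1):
        if config.flat_prior:
            profile, mu_post = _flat_posterior(alignment, t1, mu_grid, config)
            hp = None
        else:
            hp = posterior_over_hypotheses(
                alignment, library, t1, mu_grid, config, cdr3_mask=mask
            )
            profile = position_posterior(hp, pconf)
            mu_post = hp.mu_grid
        modal = profile.modal_sequence()

        if hp is not None:
            stratum, hyp = _modal_hypothesis(hp)
            mask = compute_cdr3_mask(hyp, library, stratum.scheme, alignment.length)

        if fixed_tree or alignment.n_queries == 0:
            converged = True
            break
        new_tree = estimate_tree(alignment, modal, mask, True, config.cdr3_multiplier)
        if new_tree.total_length() < 1e-8:
            # queries identical to the modal UA: nothing to re-estimate
            converged = True
            break
        t1_new, _ = unit_normalize(new_tree)
        if trees_converged(t1, t1_new, config.branch_tolerance):
            t1 = t1_new
            converged = True
            break
        t1 = t1_new

    err_vec, err_total = probable_error(profile)
    if hp is not None:
        summary, _, _ = _junction_summary(hp, profile)
        seg_post = hp.segment_posteriors
    else:
        summary, seg_post = {}, {}

    t1.mu = float(np.dot(mu_post.values, mu_post.posterior))
    return UAResult(
        modal_ua=modal,
        position_posterior=profile,
        probable_error=err_vec,
        total_probable_error=err_total,
        segment_posteriors=seg_post,
        junction_summary=summary,
        mu_posterior=mu_post,
        final_tree=t1,
        iterations=iterations,
        converged=converged,
        mutation_frequency=mutation_frequency(alignment, modal),
        alignment=alignment,
        cdr3_mask=mask,
    )


def mutation_frequency(alignment: QueryAlignment, ua: str) -> float:
    """Mean per-query mismatch percentage against the UA (gap columns excluded)."""
    ua_codes = encode(ua)
    freqs = []
    for row in alignment.matrix:
        usable = (row != GAP_CODE) & (ua_codes != GAP_CODE)
        n = int(usable.sum())
        if n:
            freqs.append(float((row[usable] != ua_codes[usable]).mean()))
    return 100.0 * float(np.mean(freqs)) if freqs else 0.0


@dataclass
class PairwiseStats:
    mean: float
    sd: float
    max: int
    n_pairs: int


def pairwise_stats(sequences: Mapping[str, str] | QueryAlignment) -> PairwiseStats:
    """Mean, sample SD, and max of pairwise nucleotide differences.

    Columns where either sequence has a gap are excluded from that pair.
    """
    if isinstance(sequences, QueryAlignment):
        mat = sequences.matrix
    else:
        aln = QueryAlignment.from_rows(dict(sequences))
        mat = aln.matrix
    n = mat.shape[0]
    if n < 2:
        raise ValueError("pairwise_stats needs at least 2 aligned sequences")
    dists = []
    for i, j in itertools.combinations(range(n), 2):
        usable = (mat[i] != GAP_CODE) & (mat[j] != GAP_CODE)
        dists.append(int((mat[i][usable] != mat[j][usable]).sum()))
    arr = np.array(dists, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return PairwiseStats(float(arr.mean()), sd, int(arr.max()), arr.size)
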