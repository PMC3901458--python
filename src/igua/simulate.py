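"""Synthetic clonal families with known ground truth.

The generator mirrors the inference model: locus-uniform segment choice,
uniform trims (with up to four P nucleotides), uniform-composition N
insertions, and independent Jukes-Cantor point mutation along a clonal tree
with a doubled rate in CDR3. It exists so every inference stage can be tested
against a known unmutated ancestor without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .germline import LibrarySet, Role, trim_range
from .inference import UAResult
from .msa import encode
from .phylo import CladeTree, Node, palm_tree, unit_normalize
from .rearrangement import (
    PriorConfig,
    RearrangementParams,
    build_ancestor_sequence,
    segment_fragment,
)

_NUC = np.array(list("ACGT"))


@dataclass
class SimulationTruth:
    """Ground truth for one simulated clone."""

    params: RearrangementParams
    ua: str
    seed: int
    tree: Optional[CladeTree] = None
    mu_true: Optional[float] = None
    sequences: dict[str, str] = field(default_factory=dict)
    events: list[tuple[str, int, str, str]] = field(default_factory=list)
    cdr3_mask: Optional[np.ndarray] = None
    library: Optional[LibrarySet] = None

    def replay(self) -> dict[str, str]:
        """Reapply recorded mutation events to the UA along the tree."""
        if self.tree is None:
            return {}
        state: dict[str, list[str]] = {}
        out: dict[str, str] = {}

        def walk(node, seq: list[str]) -> None:
            seq = seq.copy()
            for name, pos, old, new in self.events:
                if name == _node_key(node):
                    assert seq[pos] == old
                    seq[pos] = new
            if node.is_leaf:
                out[node.name] = "".join(seq)
            for child in node.children:
                walk(child, seq)

        walk(self.tree.root, list(self.ua))
        return out


def _node_key(node: Node) -> str:
    return node.name or f"@{id(node)}"


def simulate_rearrangement(
    library: LibrarySet,
    config: Optional[PriorConfig] = None,
    seed: int = 0,
    n_max_sim: int = 8,
) -> SimulationTruth:
    """Sample rearrangement parameters from the prior and assemble the UA.

    Alleles are drawn from the locus-uniform prior, trims uniformly over
    their allowed ranges (D trimming capped as in the prior, retaining at
    least one base), N lengths uniformly on [0, n_max_sim] (8 by default,
    the realistic TdT range) with i.i.d. uniform base composition.
    """
    config = config or PriorConfig()
    rng = np.random.default_rng(seed)

    def pick(lib):
        ids = [s.segment_id for s in lib]
        probs = np.array([lib.allele_prior[i] for i in ids])
        return lib.get(ids[rng.choice(len(ids), p=probs / probs.sum())])

    def pick_trim(segment) -> int:
        lo, hi = trim_range(segment)
        return int(rng.integers(lo, hi + 1))

    def pick_n() -> str:
        k = int(rng.integers(0, n_max_sim + 1))
        return "".join(rng.choice(_NUC, size=k))

    v, j = pick(library.v), pick(library.j)
    kwargs = dict(
        v_id=v.segment_id, j_id=j.segment_id,
        r_v=pick_trim(v), r_j=pick_trim(j), n1=pick_n(),
    )
    if library.d is not None:
        d = pick(library.d)
        lo, _ = trim_range(d)
        hi = min(len(d.sequence), config.d_trim_max)
        while True:
            r_d1 = int(rng.integers(lo, hi + 1))
            r_d2 = int(rng.integers(lo, hi + 1))
            if max(r_d1, 0) + max(r_d2, 0) <= len(d.sequence) - 1:
                break
        kwargs.update(d_id=d.segment_id, r_d1=r_d1, r_d2=r_d2, n2=pick_n())
    params = RearrangementParams(**kwargs)
    ua = build_ancestor_sequence(params, library)
    truth = SimulationTruth(params=params, ua=ua, seed=seed, library=library)
    truth.cdr3_mask = true_cdr3_mask(params, library)
    return truth


def true_cdr3_mask(params: RearrangementParams, library: LibrarySet) -> np.ndarray:
    """CDR3 columns of the assembled UA, from the known anchors and trims."""
    v = library.v.get(params.v_id)
    j = library.j.get(params.j_id)
    ua_len = len(build_ancestor_sequence(params, library, validate=False))
    cys_end = v.anchor + 2
    j_offset = ua_len - len(segment_fragment(j.sequence, Role.J, params.r_j))
    trp_start = j_offset + (j.anchor - params.r_j)
    mask = np.zeros(ua_len, dtype=bool)
    mask[cys_end + 1 : trp_start] = True
    return mask


def random_palm_tree(n_leaves: int, rng: np.random.Generator) -> CladeTree:
    """Palm tree with exponential(1) stem and frond lengths, unit-normalized."""
    tree = palm_tree([f"Q{i + 1:02d}" for i in range(n_leaves)])
    lengths = rng.exponential(1.0, size=n_leaves + 1)
    tree.set_branch_lengths(np.maximum(lengths, 1e-3))
    tree, _ = unit_normalize(tree)
    return tree


def random_birth_tree(n_leaves: int, rng: np.random.Generator) -> CladeTree:
    """Random rooted binary (Yule-style) topology with exponential branches."""
    nodes = [Node(f"Q{i + 1:02d}", float(max(rng.exponential(1.0), 1e-3)))
             for i in range(n_leaves)]
    while len(nodes) > 1:
        i, k = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(None, float(max(rng.exponential(1.0), 1e-3)))
        parent.add(nodes[i])
        parent.add(nodes[k])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, k)] + [parent]
    root = Node("root")
    stem = nodes[0]
    root.add(stem)
    tree = CladeTree(root)
    tree, _ = unit_normalize(tree)
    return tree


def simulate_shm_clone(
    truth: SimulationTruth,
    n_leaves: int,
    mu_true: float,
    cdr3_multiplier: float = 2.0,
    seed: int = 0,
    topology: str = "palm",
) -> SimulationTruth:
    """Evolve the UA along a random clonal tree under Jukes-Cantor.

    Sites mutate independently; CDR3 columns use ``cdr3_multiplier`` times
    the branch rate. No indels (somatic hypermutation rarely creates them).
    """
    rng = np.random.default_rng(seed)
    maker = random_palm_tree if topology == "palm" else random_birth_tree
    t1 = maker(n_leaves, rng)
    mask = truth.cdr3_mask
    ua_codes = encode(truth.ua)
    L = ua_codes.shape[0]
    events: list[tuple[str, int, str, str]] = []
    sequences: dict[str, str] = {}
    counter = [0]

    def evolve(node: Node, codes: np.ndarray) -> None:
        if node.parent is not None:
            lam = float(node.length) * mu_true
            rate = np.full(L, lam)
            if mask is not None:
                rate[mask] *= cdr3_multiplier
            p_change = 0.75 * (1.0 - np.exp(-4.0 * rate / 3.0))
            hit = rng.random(L) < p_change
            codes = codes.copy()
            if node.name is None:
                counter[0] += 1
                node.name = f"_i{counter[0]}"
            for pos in np.flatnonzero(hit):
                old = int(codes[pos])
                new = int((old + rng.integers(1, 4)) % 4)
                events.append((_node_key(node), int(pos), "ACGT"[old], "ACGT"[new]))
                codes[pos] = new
        if node.is_leaf:
            sequences[node.name] = "".join(_NUC[codes])
        for child in node.children:
            evolve(child, codes)

    evolve(t1.root, ua_codes)
    out = SimulationTruth(
        params=truth.params,
        ua=truth.ua,
        seed=seed,
        tree=t1,
        mu_true=mu_true,
        sequences=sequences,
        events=events,
        cdr3_mask=mask,
        library=truth.library,
    )
    return out


def recovery_report(truth: SimulationTruth, result: UAResult) -> dict:
    """Compare an inference result against simulation truth."""
    ua_true, ua_hat = truth.ua, result.modal_ua
    flagged = len(ua_true) != len(ua_hat)
    n = min(len(ua_true), len(ua_hat))
    mismatches = sum(1 for a, b in zip(ua_true[:n], ua_hat[:n]) if a != b)
    mismatches += abs(len(ua_true) - len(ua_hat))

    seg_correct: dict[str, bool] = {}
    truth_ids = {"v": truth.params.v_id, "j": truth.params.j_id}
    if truth.params.d_id is not None:
        truth_ids["d"] = truth.params.d_id
    for key, sid in truth_ids.items():
        # the modal gene segment is the argmax of its marginal posterior
        marginal = result.segment_posteriors.get(key.upper())
        if marginal:
            modal_sid = max(marginal.items(), key=lambda kv: kv[1])[0]
            seg_correct[key] = modal_sid == sid
        else:
            entry = result.junction_summary.get(key)
            seg_correct[key] = bool(entry and entry["segment_id"] == sid)

    trim_error = None
    n_length_error = None
    if result.junction_summary:
        js = result.junction_summary
        true_trims = [truth.params.r_v, truth.params.r_j]
        est_trims = [js["v"]["trims"][0], js["j"]["trims"][0]]
        if truth.params.d_id is not None and "d" in js:
            true_trims += [truth.params.r_d1, truth.params.r_d2]
            est_trims += js["d"]["trims"]
        trim_error = int(sum(abs(a - b) for a, b in zip(true_trims, est_trims)))
        true_n = len(truth.params.n1) + len(truth.params.n2 or "")
        est_n = js["n1"]["length"] + (js["n2"]["length"] if "n2" in js else 0)
        n_length_error = int(abs(true_n - est_n))

    return {
        "ua_mismatches": int(mismatches),
        "total_probable_error": float(result.total_probable_error),
        "segment_correct": seg_correct,
        "trim_error": trim_error,
        "n_length_error": n_length_error,
        "length_mismatch_flagged": flagged,
    }
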