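"""Ground-truth simulators: birth-death time trees, autocorrelated branch
rates, and Jukes-Cantor sequence evolution.

Everything is seeded and deterministic; independent substreams are derived
from the config seed so that tree shape, rates and sequences can be varied
independently.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .chronology import Chronogram
from .phylo_io import Alignment, Phylogram, TreeNode, _copy_subtree

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Settings for one synthetic dataset.

    Exactly one of ``crown_age`` (run the process for a fixed time span,
    variable tip count) and ``target_n`` (grow to a fixed tip count,
    variable age) must be set.
    """

    birth_rate: float
    death_rate: float = 0.0
    crown_age: Optional[float] = None
    target_n: Optional[int] = None
    rate_mean: float = 0.005  # substitutions / site / Myr
    rate_autocorr_sd: float = 0.1  # sd of log-rate change per branch
    seq_length: int = 1000
    seed: int = 0
    retry_cap: int = 1000

    def __post_init__(self) -> None:
        if not (self.birth_rate > self.death_rate >= 0):
            raise ValueError("need birth_rate > death_rate >= 0")
        if (self.crown_age is None) == (self.target_n is None):
            raise ValueError("set exactly one of crown_age and target_n")
        if self.crown_age is not None and self.crown_age <= 0:
            raise ValueError("crown_age must be > 0")
        if self.target_n is not None and self.target_n < 2:
            raise ValueError("target_n must be >= 2")
        if self.rate_mean <= 0:
            raise ValueError("rate_mean must be > 0")
        if self.rate_autocorr_sd < 0:
            raise ValueError("rate_autocorr_sd must be >= 0")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")


class _Lineage:
    __slots__ = ("children", "t_end", "extant")

    def __init__(self) -> None:
        self.children: list["_Lineage"] = []
        self.t_end: float = math.nan
        self.extant: bool = False


def _to_node(lin: _Lineage, present: float) -> Optional[TreeNode]:
    """Prune extinct subtrees and suppress unary nodes; set node ages."""
    if not lin.children:
        if not lin.extant:
            return None
        node = TreeNode()
        node.age = 0.0
        return node
    kept = [n for n in (_to_node(c, present) for c in lin.children) if n is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    node = TreeNode()
    node.age = present - lin.t_end
    for child in kept:
        node.add_child(child)
    return node


def _run_crown(cfg: SimConfig, rng: np.random.Generator) -> Optional[TreeNode]:
    b, d = cfg.birth_rate, cfg.death_rate
    root = _Lineage()
    root.t_end = 0.0
    left, right = _Lineage(), _Lineage()
    root.children = [left, right]
    active = [left, right]
    t = 0.0
    while active:
        t += rng.exponential(1.0 / (len(active) * (b + d)))
        if t >= cfg.crown_age:
            break
        i = int(rng.integers(len(active)))
        lin = active[i]
        if rng.random() < b / (b + d):
            c1, c2 = _Lineage(), _Lineage()
            lin.children = [c1, c2]
            lin.t_end = t
            active[i] = c1
            active.append(c2)
        else:
            lin.t_end = t
            active.pop(i)
    for lin in active:
        lin.extant = True
    # condition on survival of both crown lineages, so the returned root
    # is the crown node at exactly cfg.crown_age
    node = _to_node(root, cfg.crown_age)
    if node is None or node.is_leaf or node.age < cfg.crown_age:
        return None
    return node


def _run_target_n(cfg: SimConfig, rng: np.random.Generator) -> Optional[TreeNode]:
    b, d = cfg.birth_rate, cfg.death_rate
    stem = _Lineage()
    active = [stem]
    t = 0.0
    while active:
        t += rng.exponential(1.0 / (len(active) * (b + d)))
        i = int(rng.integers(len(active)))
        lin = active[i]
        if rng.random() < b / (b + d):
            c1, c2 = _Lineage(), _Lineage()
            lin.children = [c1, c2]
            lin.t_end = t
            active[i] = c1
            active.append(c2)
            if len(active) == cfg.target_n:
                # present = time of the next (unexecuted) event
                present = t + rng.exponential(
                    1.0 / (len(active) * (b + d))
                )
                for survivor in active:
                    survivor.extant = True
                node = _to_node(stem, present)
                if node is None or node.is_leaf:
                    return None
                return node
        else:
            lin.t_end = t
            active.pop(i)
    return None  # total extinction


def simulate_tree(cfg: SimConfig) -> Chronogram:
    """Simulate a constant-rate birth-death time tree conditioned on survival.

    Crown-age mode starts from the two crown lineages and returns a tree of
    exactly that crown age; target-n mode starts from a single stem lineage
    and returns the crown tree of the first ``target_n`` surviving tips.
    Node ages are in Myr; tips are labeled ``t1..tn`` in preorder.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    for _ in range(cfg.retry_cap):
        root = (
            _run_crown(cfg, rng) if cfg.crown_age is not None else _run_target_n(cfg, rng)
        )
        if root is not None:
            break
    else:
        raise RuntimeError(
            f"no surviving tree in {cfg.retry_cap} attempts; "
            "death rate too close to birth rate?"
        )
    chrono = Chronogram(root, root_age=root.age, validate=False)
    for i, tip in enumerate(chrono.tips(), start=1):
        tip.label = f"t{i}"
    chrono.validate_chronogram()
    chrono.validate()
    return chrono


def assign_rates(chrono: Chronogram, cfg: SimConfig) -> Phylogram:
    """Dress a time tree with autocorrelated branch rates.

    Each branch's rate is its parent branch's rate times a lognormal step
    exp(Normal(-sd^2/2, sd)); branches off the root start from ``rate_mean``.
    The drift correction keeps the expected rate equal to ``rate_mean`` on
    every branch. Branch lengths become rate * duration (substitutions per
    site). True ages and rates stay attached to the returned tree's nodes.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    sd = cfg.rate_autocorr_sd
    root = _copy_subtree(chrono.root)
    tree = Phylogram(root, validate=False)
    for node in tree.preorder():
        if node.parent is None:
            node.rate = None
            node.length = None
            continue
        parent_rate = (
            cfg.rate_mean if node.parent.parent is None else node.parent.rate
        )
        step = math.exp(rng.normal(-0.5 * sd * sd, sd)) if sd > 0 else 1.0
        node.rate = parent_rate * step
        node.length = node.rate * (node.parent.age - node.age)
    tree.validate()
    return tree


def _jc_p(b: float) -> float:
    """Jukes-Cantor probability that a site differs across a branch of
    length b expected substitutions per site."""
    return 0.75 * (1.0 - math.exp(-4.0 * b / 3.0))


def simulate_sequences(tree: Phylogram, cfg: SimConfig) -> Alignment:
    """Evolve sequences along a phylogram under Jukes-Cantor.

    The root sequence is uniform over A/C/G/T; each site evolves
    independently; on a branch of length b every site changes with
    probability (3/4)(1 - exp(-4b/3)), uniformly to one of the other bases.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    L = cfg.seq_length
    seqs: dict[int, np.ndarray] = {}
    labels: list[str] = []
    tip_seqs: list[str] = []
    for node in tree.preorder():
        if node.parent is None:
            seqs[id(node)] = rng.integers(0, 4, L)
        else:
            parent_seq = seqs[id(node.parent)]
            p = _jc_p(node.length)
            hit = rng.random(L) < p
            seq = parent_seq.copy()
            n_hit = int(hit.sum())
            if n_hit:
                seq[hit] = (seq[hit] + rng.integers(1, 4, n_hit)) % 4
            seqs[id(node)] = seq
        if node.is_leaf:
            labels.append(node.label)
            tip_seqs.append("".join(_BASES[seqs[id(node)]]))
    return Alignment(labels, tip_seqs)


def ground_truth_table(tree: Phylogram):
    """True node ages and branch rates as a DataFrame (tips keyed by label,
    internal nodes by postorder index)."""
    import pandas as pd

    rows = []
    for i, node in enumerate(tree.postorder()):
        rows.append(
            {
                "node_id": node.label if node.is_leaf else f"n{i}",
                "age_myr": node.age,
                "branch_rate": node.rate,
            }
        )
    return pd.DataFrame(rows, columns=["node_id", "age_myr", "branch_rate"])


def write_fixture(outdir: str | Path, cfg: SimConfig) -> dict[str, Path]:
    """Generate one full synthetic dataset and write it as plain text.

    Emits the rate-dressed phylogram (Newick), the alignment (FASTA), the
    true chronogram (Newick, durations in Myr), a ground-truth TSV of node
    ages and branch rates, and the generating config (JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrono = simulate_tree(cfg)
    phylo = assign_rates(chrono, cfg)
    aln = simulate_sequences(phylo, cfg)
    paths = {
        "phylogram": outdir / "phylogram.nwk",
        "chronogram": outdir / "chronogram_true.nwk",
        "alignment": outdir / "alignment.fasta",
        "ground_truth": outdir / "ground_truth.tsv",
        "config": outdir / "sim_config.json",
    }
    phylo.write_newick(paths["phylogram"])
    chrono.write_newick(paths["chronogram"])
    aln.to_fasta(paths["alignment"])
    ground_truth_table(phylo).to_csv(paths["ground_truth"], sep="\t", index=False)
    paths["config"].write_text(json.dumps(asdict(cfg), indent=2) + "\n")
    return paths
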