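"""Seeded synthetic inputs with the statistical structure of the study
system.

Three generators emulate the experimental inputs so every pipeline stage
is testable end to end, each returning a ground-truth manifest that lets
recovery be scored without re-simulation:

* :func:`simulate_plastome_set` — a set of plastomes diverged from a
  common ancestor along a random bifurcating tree, with SNPs everywhere,
  1-bp slippage indels concentrated at oligo(N) homopolymer runs, and
  multi-unit in-frame indels at tandem-repeat loci.  Designated causal
  repeat loci link copy-number divergence linearly to the inheritance
  phenotype.  Because the simulation knows column homology, the true
  alignment is emitted directly (gap-explicit) — no realignment step.
* :func:`simulate_crosses` — binomially sampled variegated-seedling
  counts per line and season from true biparental rates.
* :func:`simulate_lipidome` — a multi-series lipidome with lognormal
  levels, series offsets, replicate noise, per-series lipid dropout and
  planted strength-predictive lipids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import PlastomeAlignment
from .lipids import LipidMatrix

__all__ = [
    "PlastomeSimConfig",
    "PlastomeSimData",
    "simulate_plastome_set",
    "simulate_brownian",
    "simulate_crosses",
    "simulate_lipidome",
]

_BASES = np.array(list("ACGT"))

LIPID_CLASS_WEIGHTS = {
    "MGDG": 0.08, "DGDG": 0.07, "SQDG": 0.04, "PG": 0.06, "PC": 0.12,
    "PI": 0.03, "PE": 0.06, "FA": 0.08, "TAG": 0.33, "CoQ": 0.02,
    "chlorophyll": 0.06, "pheophytin": 0.05,
}


@dataclass
class PlastomeSimConfig:
    """Parameters of the plastome-set simulation.

    Rates are per unit branch length; branch lengths are exponential
    with mean ``branch_length_mean``, so a root-to-tip path carries on
    the order of ``snp_rate * ancestor_length`` substitutions per unit.
    ``noise_sd`` is relative: phenotype noise SD = noise_sd x SD of the
    genetic signal across samples.
    """

    ancestor_length: int = 20_000
    n_samples: int = 14
    snp_rate: float = 5e-4               # substitutions per bp per unit branch
    oligo_stretch_density: float = 2e-3  # homopolymer runs per bp of ancestor
    oligo_run_length: tuple[int, int] = (8, 14)
    slippage_indel_rate: float = 0.3     # 1-bp slips per oligo run per unit branch
    n_repeat_loci: int = 4
    repeat_motif_length: int = 9         # in-frame (codon-multiple) repeat unit
    repeat_units: int = 4
    repeat_indel_rate: float = 0.5       # unit-copy events per locus per unit branch
    n_causal_loci: int = 1
    causal_beta: float = 5.0             # phenotype units per changed column
    causal_rate_multiplier: float = 3.0
    noise_sd: float = 0.5                # relative to the signal SD
    branch_length_mean: float = 0.3
    reference_id: str = "REF"
    seed: int | None = None


@dataclass
class _Node:
    children: list = field(default_factory=list)
    branch: float = 0.0
    name: str = ""


def _random_join_tree(n: int, rng: np.random.Generator, mean_bl: float) -> _Node:
    nodes = [_Node(name=f"S{i + 1:02d}", branch=float(rng.exponential(mean_bl)))
             for i in range(n)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = _Node(children=[a, b], branch=float(rng.exponential(mean_bl)))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.branch = 0.0
    return root


def _newick(node: _Node) -> str:
    def fmt(nd: _Node) -> str:
        if not nd.children:
            return f"{nd.name}:{nd.branch:.6f}"
        inner = ",".join(fmt(c) for c in nd.children)
        return f"({inner}):{nd.branch:.6f}"

    return fmt(node) + ";"


@dataclass
class _Edits:
    subs: dict = field(default_factory=dict)   # pos -> base
    dels: set = field(default_factory=set)     # deleted ancestor positions
    ins: dict = field(default_factory=dict)    # pos -> inserted string after pos

    def copy(self) -> "_Edits":
        return _Edits(dict(self.subs), set(self.dels), dict(self.ins))


@dataclass
class PlastomeSimData:
    """Simulated plastome set: alignment, phylogeny, phenotypes, truth."""

    alignment: PlastomeAlignment
    tree_newick: str
    phenotypes: pd.DataFrame  # sample_id, strength, percent, strength_class
    manifest: dict

    def write(self, outdir) -> None:
        from pathlib import Path

        from .alignment import write_bed

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.alignment.to_fasta(out / "alignment.fasta")
        write_bed(out / "annotations.bed", self.alignment.annotations)
        (out / "tree.nwk").write_text(self.tree_newick + "\n")
        self.phenotypes.to_csv(out / "phenotypes.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _place_intervals(
    L: int, n: int, width: int, rng: np.random.Generator, forbidden: list
) -> list[tuple[int, int]]:
    """Place n disjoint width-bp intervals avoiding existing ones."""
    placed: list[tuple[int, int]] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > 10_000:
            raise ValueError("cannot place intervals: ancestor too short")
        s = int(rng.integers(101, L - width - 100))
        e = s + width - 1
        if all(e < a - 20 or s > b + 20 for a, b in placed + forbidden):
            placed.append((s, e))
    return sorted(placed)


def simulate_plastome_set(config: PlastomeSimConfig) -> PlastomeSimData:
    """Simulate a diverged plastome set with planted causal loci.

    The ancestor carries embedded homopolymer runs and tandem-repeat
    loci; samples evolve along a random bifurcating tree.  Each sample's
    phenotype is ``sum_l beta_l * d_l`` over causal loci (``d_l`` = the
    number of alignment columns changed within locus ``l``) plus Gaussian
    noise scaled to the signal SD.  The ancestor itself is included as
    the unmutated reference row.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = cfg.ancestor_length
    anc = rng.choice(_BASES, size=L)

    # homopolymer runs (oligo(N) stretches): slippage hotspots
    n_runs = max(1, int(round(cfg.oligo_stretch_density * L)))
    lo, hi = cfg.oligo_run_length
    run_widths = rng.integers(lo, hi + 1, size=n_runs)
    run_iv = _place_intervals(L, n_runs, int(hi), rng, [])
    oligo_runs: list[tuple[int, int, str]] = []
    for (s, _), w in zip(run_iv, run_widths):
        base = str(rng.choice(_BASES))
        e = s + int(w) - 1
        anc[s - 1 : e] = base
        oligo_runs.append((s, e, base))

    # tandem-repeat loci (in-frame multi-unit indel hotspots)
    width = cfg.repeat_motif_length * cfg.repeat_units
    repeat_iv = _place_intervals(L, cfg.n_repeat_loci, width, rng,
                                 [(s, e) for s, e, _ in oligo_runs])
    for s, e in repeat_iv:
        motif = rng.choice(_BASES, size=cfg.repeat_motif_length)
        anc[s - 1 : e] = np.tile(motif, cfg.repeat_units)
    causal_idx = rng.choice(cfg.n_repeat_loci, size=cfg.n_causal_loci, replace=False)
    causal_loci = [(repeat_iv[i], cfg.causal_beta) for i in sorted(causal_idx)]
    ancestor = "".join(anc)

    root = _random_join_tree(cfg.n_samples, rng, cfg.branch_length_mean)

    def locus_rate(iv: tuple[int, int]) -> float:
        if any(iv == civ for civ, _ in causal_loci):
            return cfg.repeat_indel_rate * cfg.causal_rate_multiplier
        return cfg.repeat_indel_rate

    def mutate(edits: _Edits, bl: float) -> _Edits:
        e = edits.copy()
        # SNPs anywhere (on surviving ancestor positions)
        k = rng.poisson(cfg.snp_rate * L * bl)
        if k:
            alive = np.array(sorted(set(range(1, L + 1)) - e.dels))
            for pos in rng.choice(alive, size=min(k, len(alive)), replace=False):
                pos = int(pos)
                current = e.subs.get(pos, ancestor[pos - 1])
                choices = [b for b in "ACGT" if b != current]
                e.subs[pos] = str(rng.choice(choices))
        # 1-bp slippage at oligo runs
        for s, en, base in oligo_runs:
            if rng.random() < 1.0 - np.exp(-cfg.slippage_indel_rate * bl):
                if rng.random() < 0.5:
                    e.ins[en] = e.ins.get(en, "") + base
                else:
                    alive = [p for p in range(s, en + 1) if p not in e.dels]
                    if alive:
                        e.dels.add(alive[-1])
        # multi-unit in-frame indels at repeat loci
        for s, en in repeat_iv:
            if rng.random() < 1.0 - np.exp(-locus_rate((s, en)) * bl):
                units = int(rng.integers(1, 3))
                span = units * cfg.repeat_motif_length
                alive = [p for p in range(s, en + 1) if p not in e.dels]
                if rng.random() < 0.5 and len(alive) >= span + cfg.repeat_motif_length:
                    e.dels.update(alive[-span:])
                else:
                    motif = ancestor[en - cfg.repeat_motif_length : en]
                    e.ins[en] = e.ins.get(en, "") + motif * units
        return e

    tips: dict[str, _Edits] = {}

    def descend(node: _Node, edits: _Edits) -> None:
        mine = mutate(edits, node.branch) if node.branch > 0 else edits.copy()
        if not node.children:
            tips[node.name] = mine
        for child in node.children:
            descend(child, mine)

    descend(root, _Edits())
    sample_ids = sorted(tips)

    # build the gap-explicit true alignment (reference = ancestor)
    ins_width = {
        pos: max((len(tips[s].ins.get(pos, "")) for s in sample_ids), default=0)
        for pos in range(0, L + 1)
    }
    rows: dict[str, list[str]] = {cfg.reference_id: []}
    for s in sample_ids:
        rows[s] = []

    def emit_insertion_block(pos: int) -> None:
        m = ins_width[pos]
        if not m:
            return
        rows[cfg.reference_id].append("-" * m)
        for s in sample_ids:
            frag = tips[s].ins.get(pos, "")
            rows[s].append(frag + "-" * (m - len(frag)))

    emit_insertion_block(0)
    for pos in range(1, L + 1):
        rows[cfg.reference_id].append(ancestor[pos - 1])
        for s in sample_ids:
            ed = tips[s]
            if pos in ed.dels:
                rows[s].append("-")
            else:
                rows[s].append(ed.subs.get(pos, ancestor[pos - 1]))
        emit_insertion_block(pos)

    annotations = [
        (f"repeat_locus_{i + 1}", s, e, "+") for i, (s, e) in enumerate(repeat_iv)
    ] + [(f"oligo_run_{i + 1}", s, e, "+") for i, (s, e, _) in enumerate(oligo_runs)]
    alignment = PlastomeAlignment(
        sample_ids=[cfg.reference_id] + sample_ids,
        rows=["".join(rows[cfg.reference_id])] + ["".join(rows[s]) for s in sample_ids],
        reference_id=cfg.reference_id,
        annotations=annotations,
    )

    # planted per-locus divergence (alignment columns changed in locus)
    def planted_divergence(sample: str, iv: tuple[int, int]) -> int:
        s, e = iv
        ed = tips[sample]
        d = sum(1 for p in ed.subs if s <= p <= e)
        d += sum(1 for p in ed.dels if s <= p <= e)
        d += sum(len(frag) for p, frag in ed.ins.items() if s <= p <= e)
        return d

    div = {
        sample: {f"{iv[0]}-{iv[1]}": planted_divergence(sample, iv)
                 for iv, _ in causal_loci}
        for sample in sample_ids
    }
    signal = np.array(
        [sum(beta * planted_divergence(s, iv) for iv, beta in causal_loci)
         for s in sample_ids],
        dtype=float,
    )
    sd = signal.std()
    noise_scale = cfg.noise_sd * (sd if sd > 0 else 1.0)
    strength = signal + rng.normal(0.0, noise_scale, size=len(sample_ids))
    span = strength.max() - strength.min()
    percent = (
        2.0 + 96.0 * (strength - strength.min()) / span
        if span > 0 else np.full_like(strength, 50.0)
    )
    classes = np.clip(np.searchsorted(
        np.quantile(strength, [0.2, 0.4, 0.6, 0.8]), strength, side="right"
    ) + 1, 1, 5)
    phenotypes = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "strength": strength,
            "percent": percent,
            "strength_class": classes,
            "direction": "high_value_means_weak",
        }
    )
    manifest = {
        "seed": cfg.seed,
        "ancestor_length": L,
        "causal_loci": [
            {"start": iv[0], "end": iv[1], "beta": beta} for iv, beta in causal_loci
        ],
        "repeat_loci": [{"start": s, "end": e} for s, e in repeat_iv],
        "n_oligo_runs": len(oligo_runs),
        "planted_divergence": div,
        "true_strength": dict(zip(sample_ids, signal.tolist())),
        "noise_sd_absolute": float(noise_scale),
    }
    return PlastomeSimData(
        alignment=alignment,
        tree_newick=_newick(root),
        phenotypes=phenotypes,
        manifest=manifest,
    )


def simulate_brownian(tree_newick: str, seed=None, rate: float = 1.0) -> pd.Series:
    """Simulate one Brownian-motion trait on a newick tree: each branch
    adds N(0, rate * branch_length) noise; returns tip values."""
    import dendropy

    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    rng = np.random.default_rng(seed)
    value: dict = {}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        parent = value.get(node.parent_node, 0.0)
        bl = node.edge.length or 0.0
        value[node] = parent + rng.normal(0.0, np.sqrt(rate * bl)) if bl > 0 else parent
        if node.is_leaf():
            out[node.taxon.label] = value[node]
    return pd.Series(out)


def simulate_crosses(
    true_biparental_rates: dict[str, float],
    n_total: int = 200,
    n_seasons: int = 3,
    seed=None,
) -> pd.DataFrame:
    """Binomially sampled variegated-seedling counts per line and season."""
    rng = np.random.default_rng(seed)
    rows = []
    for line, rate in true_biparental_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {line!r} outside [0, 1]: {rate}")
        for season in range(1, n_seasons + 1):
            v = int(rng.binomial(n_total, rate))
            rows.append((line, f"season{season}", v, n_total))
    return pd.DataFrame(rows, columns=["line", "season", "variegated", "total"])


def simulate_lipidome(
    n_genotypes: int = 16,
    n_replicates: int = 5,
    n_series: int = 3,
    n_lipids_total: int = 184,
    n_shared: int = 102,
    n_planted: int = 8,
    planted_beta: float = 1.0,
    series_offset_sd: float = 0.5,
    noise_sd: float = 0.5,
    baseline_mean: float = 2.0,
    baseline_sd: float = 1.0,
    seed=None,
) -> tuple[LipidMatrix, dict]:
    """Simulate a multi-series lipidome with planted predictive lipids.

    Genotype inheritance classes cycle through 1..5 so every class is
    represented and each series keeps a class-1 genotype for centering.
    Log-levels are ``baseline + series offset + beta * class + noise``;
    per-series dropout of non-shared lipids yields exactly ``n_shared``
    lipids measured in all series.
    """
    if n_genotypes < 4:
        raise ValueError("need at least 4 genotypes")
    if not 0 < n_shared <= n_lipids_total:
        raise ValueError("need 0 < n_shared <= n_lipids_total")
    if n_planted > n_shared:
        raise ValueError("planted lipids must be among the shared set")
    rng = np.random.default_rng(seed)
    genotypes = [f"G{i + 1:02d}" for i in range(n_genotypes)]
    classes = {g: (i % 5) + 1 for i, g in enumerate(genotypes)}

    lipids = [f"L{i + 1:03d}" for i in range(n_lipids_total)]
    names = list(LIPID_CLASS_WEIGHTS)
    weights = np.array(list(LIPID_CLASS_WEIGHTS.values()))
    lipid_class = pd.Series(
        rng.choice(names, size=n_lipids_total, p=weights / weights.sum()), index=lipids
    )
    shared = list(rng.choice(lipids, size=n_shared, replace=False))
    measured_in: dict[str, set[int]] = {l: set(range(1, n_series + 1)) for l in shared}
    for l in lipids:
        if l in measured_in:
            continue
        k = int(rng.integers(1, n_series))  # proper subset: missing somewhere
        measured_in[l] = set(rng.choice(range(1, n_series + 1), size=k, replace=False))

    planted = sorted(rng.choice(shared, size=n_planted, replace=False))
    beta = pd.Series(0.0, index=lipids)
    for i, l in enumerate(planted):
        beta[l] = planted_beta * (1 if i % 2 == 0 else -1)
    baseline = pd.Series(rng.normal(baseline_mean, baseline_sd, n_lipids_total), index=lipids)
    offsets = {
        (s, l): float(rng.normal(0.0, series_offset_sd))
        for s in range(1, n_series + 1)
        for l in lipids
    }

    # every genotype is measured in every series (class-1 presence guaranteed)
    rows, meta_rows = [], []
    for s in range(1, n_series + 1):
        for g in genotypes:
            for rep in range(1, n_replicates + 1):
                sid = f"{g}_s{s}_r{rep}"
                level = {}
                for l in lipids:
                    if s not in measured_in[l]:
                        level[l] = np.nan
                        continue
                    log_level = (
                        baseline[l]
                        + offsets[(s, l)]
                        + beta[l] * classes[g]
                        + rng.normal(0.0, noise_sd)
                    )
                    level[l] = float(np.exp(log_level))
                rows.append(pd.Series(level, name=sid))
                meta_rows.append(
                    {"sample_id": sid, "genotype": g, "series": s,
                     "replicate": rep, "inheritance_class": classes[g]}
                )
    levels = pd.DataFrame(rows)[lipids]
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = LipidMatrix(levels=levels, samples=samples, lipid_classes=lipid_class)
    manifest = {
        "seed": seed,
        "planted_lipids": {l: float(beta[l]) for l in planted},
        "shared_lipids": sorted(shared),
        "n_shared": n_shared,
        "genotype_classes": classes,
    }
    return matrix, manifest
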