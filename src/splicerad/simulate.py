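"""Truth-known synthetic datasets emulating a multi-radiation RNA-seq design.

The generator emits the full study layout by default: 20 species in four
clades (three lake radiations, LV/LM/LT, of six species each, plus two
nonradiating riverine lineages, NR), two jaw tissues (OJ, PJ), and five
biological replicates per species per tissue — 200 samples.

The generative model, top down:

1. Per-gene species-level log2 expression evolves along the species tree
   under an Ornstein-Uhlenbeck process (stabilizing selection; the default
   for 90% of genes) or Brownian motion (neutral drift).  The OU root is
   drawn from the stationary distribution N(theta, sigma2/(2*alpha)) so that
   the tip covariance takes the stationary form assumed by the fitter.
2. Tissue and clade effects are additive log2 offsets drawn independently
   per gene (zero mean); differential-expression effects are guild-specific
   log2 offsets planted in chosen radiations.
3. Isoform usage: each gene's isoform proportions come from a Dirichlet
   base, perturbed on the logit scale per clade (clade-structured splicing)
   and per species (within-clade jitter).  Differential-splicing effects
   shift a focal isoform's PSI between guilds; "novel" isoforms are
   structural zeros outside their radiation (not sampling zeros), with the
   remaining mass renormalized.
4. Counts: per replicate, gene-level counts are negative binomial around
   the expression-derived mean scaled to the target library size; isoform
   counts are multinomial given the gene count and the species' isoform
   proportions.

Everything planted is recorded in truth tables so downstream stages can be
scored against known answers.  The same seed and config always produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io import CountMatrix, write_counts, write_iso2gene
from .trees import read_tree, tip_labels

RADIATIONS = ("LV", "LM", "LT")
NR_CLADE = "NR"

_PSI_CEIL = 0.92  # headroom so planted shifts never pin an isoform at 1
_PSI_FLOOR = 0.02


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# study-like species tree


def default_study_tree() -> str:
    """Newick for the default 20-tip study-like ultrametric tree (height 1).

    Topology: (LT, (LM, (NR, LV))), giving clade stem ages LT 1.0 > LM 0.8 >
    LV 0.6, with radiation crown ages LT 0.55 > LM 0.45 > LV 0.30 and an NR
    cherry of crown age 0.30.
    """

    def radiation(prefix: str, crown: float) -> tuple[str, float]:
        a, b, d, c = 0.4 * crown, 0.3 * crown, 0.35 * crown, 0.65 * crown
        t = (
            f"({prefix}1:{a:.6f},{prefix}2:{a:.6f}):{crown - a:.6f},"
            f"(({prefix}3:{b:.6f},{prefix}4:{b:.6f}):{c - b:.6f},"
            f"({prefix}5:{d:.6f},{prefix}6:{d:.6f}):{c - d:.6f}):{crown - c:.6f}"
        )
        return f"({t})", crown

    lv, lv_crown = radiation("LV", 0.30)
    lm, lm_crown = radiation("LM", 0.45)
    lt, lt_crown = radiation("LT", 0.55)
    nr, nr_crown = "(NR1:0.30,NR2:0.30)", 0.30
    inner = f"({nr}:{0.6 - nr_crown:.6f},{lv}:{0.6 - lv_crown:.6f})"
    mid = f"({lm}:{0.8 - lm_crown:.6f},{inner}:{0.8 - 0.6:.6f})"
    return f"({lt}:{1.0 - lt_crown:.6f},{mid}:{1.0 - 0.8:.6f});"


def default_species_table(tree: dendropy.Tree) -> pd.DataFrame:
    """Species/clade/guild assignments derived from tip labels.

    Clade is the two-letter label prefix.  Within each radiation,
    odd-numbered species are herbivores and even-numbered carnivores (so
    guild cuts across subclades); nonradiating species are 'other' and take
    part in no guild contrast.
    """
    rows = []
    for sp in tip_labels(tree):
        clade = sp[:2]
        if clade == NR_CLADE:
            guild = "other"
        else:
            guild = "herbivore" if int(sp[2:]) % 2 == 1 else "carnivore"
        rows.append({"species": sp, "clade": clade, "guild": guild})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    """Parameters of the generative model (defaults = study-like design)."""

    tree_spec: str | None = None  # newick; None -> default_study_tree()
    n_genes: int = 500
    #: distribution of isoform count per gene over {1..5}
    isoforms_per_gene: dict = field(
        default_factory=lambda: {1: 0.40, 2: 0.30, 3: 0.15, 4: 0.10, 5: 0.05}
    )
    frac_ou: float = 0.9
    alpha_range: tuple = (2.0, 8.0)  # per unit tree height
    sigma2_range: tuple = (0.2, 2.0)  # OU diffusion, log2^2 units
    bm_sigma2_range: tuple = (0.05, 0.5)
    theta_range: tuple = (4.0, 9.0)  # log2 expression optima / BM roots
    tissue_effect_sd: float = 1.5  # log2 units
    clade_effect_sd: float = 0.5
    psi_clade_logit_sd: float = 1.0
    psi_species_logit_sd: float = 0.25
    base_concentration: float = 1.5
    frac_deg: float = 0.10
    deg_log2fc: float = 2.0
    frac_deg_all_radiations: float = 0.2  # of DEGs: planted 3-way convergent
    frac_dsg: float = 0.10
    dsg_delta_psi: float = 0.3
    frac_dsg_two_radiations: float = 0.2  # of DSGs: 2-way convergent
    frac_novel: float = 0.02  # per radiation, of multi-isoform genes
    novel_floor: float = 0.15  # minimum usage of a novel isoform in its clade
    n_replicates: int = 5
    library_size_mean: float = 3e5
    library_size_sd: float = 0.1  # lognormal sd of per-sample depth factor
    nb_dispersion: float = 0.05
    psi_delta_threshold: float = 0.2  # used for truth trajectory classes
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_ou", "frac_deg", "frac_dsg", "frac_novel",
            "frac_deg_all_radiations", "frac_dsg_two_radiations",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.alpha_range[0] <= 0:
            raise SimulationError("alpha_range must be positive")
        if self.nb_dispersion < 0:
            raise SimulationError("nb_dispersion must be >= 0")
        total = sum(self.isoforms_per_gene.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError("isoforms_per_gene must sum to 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["isoforms_per_gene"] = {int(k): v for k, v in d["isoforms_per_gene"].items()}
        return d


# ---------------------------------------------------------------------------
# trait evolution on the tree


def _tip_matrix(
    tree: dendropy.Tree,
    regimes: np.ndarray,
    alpha: np.ndarray,
    sigma2: np.ndarray,
    theta: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate G traits on the tree; returns (G, n_tips) in tip order.

    ``theta`` holds the OU optimum for OU rows and the fixed root value for
    BM rows.  One normal deviate per (node, gene) is consumed in preorder,
    which makes output deterministic for a given generator state.
    """
    is_ou = regimes == "OU"
    if (alpha[is_ou] <= 0).any():
        raise SimulationError("OU requires alpha > 0")
    if (sigma2 < 0).any():
        raise SimulationError("sigma2 must be >= 0")
    values: dict = {}
    tips = {}
    for node in tree.preorder_node_iter():
        z = rng.standard_normal(len(regimes))
        if node.parent_node is None:
            sd = np.where(is_ou, np.sqrt(sigma2 / (2.0 * alpha)), 0.0)
            values[node] = theta + sd * z
        else:
            t = node.edge.length or 0.0
            if t < 0:
                raise SimulationError("negative branch length")
            parent = values[node.parent_node]
            decay = np.exp(-alpha * t)
            ou_mean = theta + (parent - theta) * decay
            ou_sd = np.sqrt(sigma2 * (1.0 - decay**2) / (2.0 * alpha))
            bm_sd = np.sqrt(sigma2 * t)
            mean = np.where(is_ou, ou_mean, parent)
            sd = np.where(is_ou, ou_sd, bm_sd)
            values[node] = mean + sd * z
        if node.is_leaf():
            tips[node.taxon.label] = values[node]
    labels = tip_labels(tree)
    return np.column_stack([tips[lab] for lab in labels])


def simulate_tip_expression(
    tree: dendropy.Tree,
    regime: str,
    params: dict,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Species-level log2 expression for one gene under OU or BM.

    Parameters
    ----------
    regime
        ``"OU"`` (params: alpha, sigma2, theta; root drawn from the
        stationary distribution) or ``"BM"`` (params: sigma2, root).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if regime not in ("OU", "BM"):
        raise SimulationError(f"unknown regime {regime!r}")
    if regime == "OU":
        alpha = float(params["alpha"])
        if alpha <= 0:
            raise SimulationError("OU requires alpha > 0")
        theta = float(params["theta"])
    else:
        alpha = 1.0  # unused for BM rows
        theta = float(params["root"])
    out = _tip_matrix(
        tree,
        np.array([regime]),
        np.array([alpha]),
        np.array([float(params["sigma2"])]),
        np.array([theta]),
        rng,
    )
    return pd.Series(out[0], index=tip_labels(tree))


# ---------------------------------------------------------------------------
# isoform proportions


def _shift_focal(p: np.ndarray, delta: float, focal: int) -> np.ndarray:
    """Raise (or lower) the focal isoform's proportion by ``delta``.

    Implemented as a logit-scale shift of the focal component solved to land
    on the target proportion, with the other components scaled to keep the
    vector on the simplex.  Clipped to [_PSI_FLOOR, _PSI_CEIL].
    """
    p = np.asarray(p, dtype=float)
    target = float(np.clip(p[focal] + delta, _PSI_FLOOR, _PSI_CEIL))
    out = p.copy()
    if len(p) == 1:
        return out
    rest = 1.0 - p[focal]
    if rest <= 0:
        return out
    out *= (1.0 - target) / rest
    out[focal] = target
    return out


def simulate_isoform_proportions(
    n_iso: int,
    base_concentration: float,
    guild_effect: float = 0.0,
    novel_flags: dict | None = None,
    seed: int | np.random.Generator = 0,
    clades: tuple = (NR_CLADE,) + RADIATIONS,
    guilds: tuple = ("herbivore", "carnivore"),
    focal: int | None = None,
) -> pd.DataFrame:
    """Per-clade-per-guild isoform proportion vectors for one gene.

    Draws a Dirichlet base vector and applies (i) a guild effect — a
    logit-scale shift of the focal isoform sized to change its PSI by
    ``guild_effect`` in herbivores relative to carnivores — and (ii) novel
    structural zeros: ``novel_flags`` maps clade -> iterable of isoform
    indices absent in that clade (mass renormalized over the rest).

    Returns a DataFrame indexed by (clade, guild); rows sum to 1.
    """
    if n_iso < 1:
        raise SimulationError("n_iso must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = (
        np.ones(1)
        if n_iso == 1
        else rng.dirichlet(np.full(n_iso, base_concentration))
    )
    if focal is None:
        focal = int(np.argmin(base))
    novel_flags = novel_flags or {}
    rows = {}
    for clade in clades:
        for guild in guilds:
            p = base.copy()
            if guild_effect and clade != NR_CLADE and guild == "herbivore":
                p = _shift_focal(p, guild_effect, focal)
            absent = list(novel_flags.get(clade, ()))
            if absent:
                if len(absent) >= n_iso:
                    raise SimulationError(
                        f"all isoforms flagged absent for clade {clade}"
                    )
                p = p.copy()
                p[absent] = 0.0
                total = p.sum()
                if total <= 0:
                    raise SimulationError(
                        f"all isoform mass removed for clade {clade}"
                    )
                p /= total
            rows[(clade, guild)] = p
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["clade", "guild"])
    return out


def _logit_jitter(p: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Perturb a proportion vector on the log scale (softmax renormalized).

    Structural zeros stay exactly zero.
    """
    if sd <= 0 or len(p) == 1:
        return p.copy()
    live = p > 0
    out = np.zeros_like(p)
    z = rng.standard_normal(len(p))
    w = np.where(live, np.log(np.clip(p, 1e-300, None)) + sd * z, -np.inf)
    w_live = np.exp(w[live] - w[live].max())
    out[live] = w_live / w_live.sum()
    return out


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    expr_by_group: pd.DataFrame,
    proportions: pd.DataFrame,
    iso2gene: pd.Series,
    n_replicates: int = 5,
    library_size_mean: float = 3e5,
    nb_dispersion: float = 0.05,
    seed: int | np.random.Generator = 0,
    library_size_sd: float = 0.1,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Sample an isoform count matrix from group-level expression and PSI.

    Parameters
    ----------
    expr_by_group
        genes x (species, tissue) log2 expression (MultiIndex columns).
    proportions
        isoform x species true isoform proportions (per-gene columns sum
        to 1 within each species wherever the gene has isoforms).
    n_replicates
        replicates per (species, tissue) group.

    Gene-level replicate counts are NegBin(mean = depth-scaled 2^log2expr,
    dispersion); with dispersion 0 the limit is Poisson.  Isoform counts are
    Multinomial(gene count, species proportions), so isoform counts of a
    gene always sum to the gene count exactly.

    Returns the CountMatrix and a metadata frame (one row per sample).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if library_size_mean <= 0:
        raise SimulationError("zero or negative library size")
    genes = expr_by_group.index.to_numpy()
    iso_ids = proportions.index.to_numpy()
    gene_of_iso = iso2gene.reindex(iso_ids).to_numpy()
    order = {g: i for i, g in enumerate(genes)}
    gene_idx = np.array([order[g] for g in gene_of_iso])

    # padded (gene, max_iso) proportion tensor per species for vectorized
    # multinomial splitting
    max_iso = int(pd.Series(gene_of_iso).value_counts().max())
    iso_slot = np.zeros(len(iso_ids), dtype=int)
    seen: dict = {}
    for k, g in enumerate(gene_of_iso):
        iso_slot[k] = seen.get(g, 0)
        seen[g] = iso_slot[k] + 1

    columns: dict = {}
    meta_rows = []
    for species, tissue in expr_by_group.columns:
        log2mu = expr_by_group[(species, tissue)].to_numpy()
        raw = np.exp2(log2mu)
        pvals = np.zeros((len(genes), max_iso))
        pvals[gene_idx, iso_slot] = proportions[species].to_numpy()
        single = pvals.sum(axis=1) <= 0  # genes absent from proportions
        pvals[single, 0] = 1.0
        for rep in range(1, n_replicates + 1):
            depth = library_size_mean * rng.lognormal(
                -0.5 * library_size_sd**2, library_size_sd
            )
            mu = raw / raw.sum() * depth
            if nb_dispersion < 1e-9:
                gene_counts = rng.poisson(mu)
            else:
                r = 1.0 / nb_dispersion
                gene_counts = rng.negative_binomial(r, r / (r + mu))
            iso_counts = rng.multinomial(gene_counts, pvals)
            sample_id = f"{species}_{tissue}_{rep}"
            columns[sample_id] = iso_counts[gene_idx, iso_slot]
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "species": species,
                    "tissue": tissue,
                    "replicate": rep,
                }
            )
    values = pd.DataFrame(columns, index=iso_ids)
    metadata = pd.DataFrame(meta_rows)
    return CountMatrix(values=values, iso2gene=iso2gene.reindex(iso_ids)), metadata


# ---------------------------------------------------------------------------
# trajectory truth


def trajectory_class(
    present_nr: bool, present_rad: bool, delta: float, threshold: float
) -> str:
    """Decision table mapping (presence_NR, presence_radiation, dPSI) to a
    trajectory class.  Total and mutually exclusive by construction."""
    if present_nr:
        if delta > threshold:
            return "ancestral-gain"
        if delta < -threshold:
            return "ancestral-loss"
        return "stable-ancestral"
    if present_rad:
        return "novel-gain" if delta > threshold else "novel-low"
    return "absent"


# ---------------------------------------------------------------------------
# full dataset


@dataclass
class SimulatedDataset:
    """A complete truth-known dataset."""

    counts: CountMatrix
    metadata: pd.DataFrame  # indexed by sample_id
    tree_newick: str
    true_psi: pd.DataFrame  # isoform x species true proportions (clade+species level)
    gene_truth: pd.DataFrame
    iso_truth: pd.DataFrame
    species_table: pd.DataFrame
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": out / "counts.tsv",
            "iso2gene": out / "iso2gene.tsv",
            "metadata": out / "metadata.tsv",
            "tree": out / "tree.nwk",
            "gene_truth": out / "truth_genes.tsv",
            "iso_truth": out / "truth_isoforms.tsv",
            "true_psi": out / "truth_psi.tsv",
        }
        write_counts(self.counts, paths["counts"])
        write_iso2gene(self.counts.iso2gene, paths["iso2gene"])
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        paths["tree"].write_text(self.tree_newick + "\n")
        self.gene_truth.to_csv(paths["gene_truth"], sep="\t", index=False)
        self.iso_truth.to_csv(paths["iso_truth"], sep="\t", index=False)
        self.true_psi.rename_axis("isoform_id").to_csv(paths["true_psi"], sep="\t")
        return paths


def _assign_radiations(
    n: int, frac_all: float, rng: np.random.Generator, two_way_frac: float = 0.0
) -> list[tuple[str, ...]]:
    """Radiation assignment for n planted features: a fixed fraction gets
    all three radiations (convergent), optionally a fraction gets two, the
    rest cycle through single radiations."""
    n_all = round(frac_all * n)
    n_two = round(two_way_frac * n)
    out: list[tuple[str, ...]] = []
    pairs = [("LV", "LM"), ("LV", "LT"), ("LM", "LT")]
    for i in range(n):
        if i < n_all:
            out.append(RADIATIONS)
        elif i < n_all + n_two:
            out.append(pairs[i % 3])
        else:
            out.append((RADIATIONS[i % 3],))
    return out


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate the full dataset described by ``config`` (see module docs)."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    newick = cfg.tree_spec or default_study_tree()
    tree = read_tree(newick, is_path=False)
    species_table = default_species_table(tree)
    species = species_table["species"].tolist()
    clades = dict(zip(species_table["species"], species_table["clade"]))
    guilds = dict(zip(species_table["species"], species_table["guild"]))

    G = cfg.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(1, G + 1)])

    # --- per-gene regime and parameters -----------------------------------
    n_ou = round(cfg.frac_ou * G)
    regimes = np.array(["OU"] * n_ou + ["BM"] * (G - n_ou))
    rng.shuffle(regimes)
    alpha = rng.uniform(*cfg.alpha_range, G)
    sigma2 = np.where(
        regimes == "OU",
        rng.uniform(*cfg.sigma2_range, G),
        rng.uniform(*cfg.bm_sigma2_range, G),
    )
    theta = rng.uniform(*cfg.theta_range, G)  # optimum (OU) or root (BM)
    tips = _tip_matrix(tree, regimes, alpha, sigma2, theta, rng)  # (G, S)
    tip_order = tip_labels(tree)
    sp_col = {sp: i for i, sp in enumerate(tip_order)}

    # --- isoform structure -------------------------------------------------
    iso_levels = np.array(sorted(cfg.isoforms_per_gene))
    iso_probs = np.array([cfg.isoforms_per_gene[k] for k in iso_levels], float)
    n_iso = rng.choice(iso_levels, size=G, p=iso_probs / iso_probs.sum())
    multi = np.flatnonzero(n_iso > 1)

    # --- planted differential expression ----------------------------------
    n_deg = round(cfg.frac_deg * G)
    deg_order = rng.permutation(G)[:n_deg]
    deg_radiations = _assign_radiations(n_deg, cfg.frac_deg_all_radiations, rng)
    de_status = {r: np.zeros(G, bool) for r in RADIATIONS}
    de_dir = {r: np.array([""] * G, dtype=object) for r in RADIATIONS}
    for k, g in enumerate(deg_order):
        direction = "herbivore" if k % 2 == 0 else "carnivore"
        for r in deg_radiations[k]:
            de_status[r][g] = True
            de_dir[r][g] = direction

    # --- planted differential splicing ------------------------------------
    n_dsg = round(cfg.frac_dsg * len(multi))
    dsg_order = rng.permutation(multi)[:n_dsg]
    dsg_radiations = _assign_radiations(
        n_dsg, 0.0, rng, two_way_frac=cfg.frac_dsg_two_radiations
    )
    ds_status = {r: np.zeros(G, bool) for r in RADIATIONS}
    ds_dir = {r: np.array([""] * G, dtype=object) for r in RADIATIONS}
    ds_focal = np.full(G, -1, dtype=int)
    for k, g in enumerate(dsg_order):
        direction = "herbivore" if k % 2 == 0 else "carnivore"
        for r in dsg_radiations[k]:
            ds_status[r][g] = True
            ds_dir[r][g] = direction

    # --- planted novel isoforms -------------------------------------------
    n_novel_per_rad = round(cfg.frac_novel * len(multi))
    candidates = rng.permutation(np.setdiff1d(multi, dsg_order))
    novel_gene: dict[int, str] = {}  # gene index -> radiation
    pos = 0
    for r in RADIATIONS:
        for _ in range(n_novel_per_rad):
            if pos >= len(candidates):
                break
            novel_gene[int(candidates[pos])] = r
            pos += 1

    # --- per-species isoform proportions ----------------------------------
    clade_list = (NR_CLADE,) + RADIATIONS
    iso_ids: list[str] = []
    iso_gene: list[str] = []
    novel_in: list[str] = []
    psi_cols = {sp: [] for sp in species}
    clade_mean_psi = {c: [] for c in clade_list}

    for g in range(G):
        k = int(n_iso[g])
        if k == 1:
            base = np.ones(1)
        else:
            base = rng.dirichlet(np.full(k, cfg.base_concentration))
        focal = int(np.argmin(base))
        novel_slot = -1
        if g in novel_gene:
            # the novel isoform is the last slot unless it is the DS focal
            novel_slot = k - 1 if focal != k - 1 else k - 2
        ds_focal[g] = focal

        # clade-level proportions (logit-perturbed base)
        clade_p = {}
        for c in clade_list:
            p = _logit_jitter(base, cfg.psi_clade_logit_sd if k > 1 else 0.0, rng)
            if novel_slot >= 0 and c != novel_gene[g]:
                p[novel_slot] = 0.0
                p /= p.sum()
            elif novel_slot >= 0:
                if p[novel_slot] < cfg.novel_floor:
                    p = _shift_focal(p, cfg.novel_floor - p[novel_slot], novel_slot)
            clade_p[c] = p

        # species-level proportions with planted guild shifts
        sp_p = {}
        for sp in species:
            c = clades[sp]
            p = _logit_jitter(clade_p[c], cfg.psi_species_logit_sd if k > 1 else 0.0, rng)
            if c in RADIATIONS and ds_status[c][g]:
                if guilds[sp] == ds_dir[c][g]:
                    p = _shift_focal(p, cfg.dsg_delta_psi, focal)
            sp_p[sp] = p
        for sp in species:
            psi_cols[sp].append(sp_p[sp])

        # clade means of the species-level truth (what an infinitely deep
        # experiment would measure per clade)
        for c in clade_list:
            members = [sp for sp in species if clades[sp] == c]
            clade_mean_psi[c].append(
                np.mean([sp_p[sp] for sp in members], axis=0)
            )

        for j in range(k):
            iso_ids.append(f"{gene_ids[g]}_i{j + 1}")
            iso_gene.append(gene_ids[g])
            novel_in.append(novel_gene[g] if j == novel_slot else "")

    iso_index = pd.Index(iso_ids, name="isoform_id")
    iso2gene = pd.Series(iso_gene, index=iso_index, name="gene_id")
    true_psi = pd.DataFrame(
        {sp: np.concatenate(psi_cols[sp]) for sp in species}, index=iso_index
    )
    clade_psi = pd.DataFrame(
        {c: np.concatenate(clade_mean_psi[c]) for c in clade_list}, index=iso_index
    )

    # --- expression offsets and planted DE --------------------------------
    tissue_off = rng.normal(0.0, cfg.tissue_effect_sd, G)  # applied to PJ
    clade_off = {c: rng.normal(0.0, cfg.clade_effect_sd, G) for c in clade_list}

    cols = {}
    for sp in species:
        c = clades[sp]
        base_expr = tips[:, sp_col[sp]] + clade_off[c]
        de = np.zeros(G)
        if c in RADIATIONS:
            sign = np.where(de_dir[c] == guilds[sp], 1.0, -1.0)
            de = np.where(de_status[c], sign * cfg.deg_log2fc / 2.0, 0.0)
        for tissue in ("OJ", "PJ"):
            cols[(sp, tissue)] = base_expr + de + (tissue_off if tissue == "PJ" else 0.0)
    expr_by_group = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    expr_by_group.columns = pd.MultiIndex.from_tuples(
        expr_by_group.columns, names=["species", "tissue"]
    )

    counts, metadata = simulate_counts(
        expr_by_group,
        true_psi,
        iso2gene,
        n_replicates=cfg.n_replicates,
        library_size_mean=cfg.library_size_mean,
        nb_dispersion=cfg.nb_dispersion,
        seed=rng,
        library_size_sd=cfg.library_size_sd,
    )
    metadata["clade"] = metadata["species"].map(clades)
    metadata["guild"] = metadata["species"].map(guilds)
    metadata = metadata[
        ["sample_id", "species", "clade", "tissue", "guild", "replicate"]
    ].set_index("sample_id", drop=False)

    # --- truth tables ------------------------------------------------------
    gene_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "regime": regimes,
            "alpha": np.where(regimes == "OU", alpha, np.nan),
            "sigma2": sigma2,
            "theta": theta,
            "evolutionary_variance": np.where(
                regimes == "OU", sigma2 / (2.0 * alpha), np.nan
            ),
            "n_isoforms": n_iso,
        }
    )
    for r in RADIATIONS:
        gene_truth[f"de_{r}"] = de_status[r]
        gene_truth[f"de_dir_{r}"] = de_dir[r]
        gene_truth[f"ds_{r}"] = ds_status[r]
        gene_truth[f"ds_dir_{r}"] = ds_dir[r]

    iso_truth = pd.DataFrame(
        {"isoform_id": iso_ids, "gene_id": iso_gene, "novel_in": novel_in}
    )
    thr = cfg.psi_delta_threshold
    present = clade_psi > 0  # structural presence
    nr_mean = clade_psi[NR_CLADE].to_numpy()
    nr_present = present[NR_CLADE].to_numpy()
    for r in RADIATIONS:
        r_mean = clade_psi[r].to_numpy()
        r_present = present[r].to_numpy()
        delta = np.where(nr_present, r_mean - nr_mean, r_mean)
        iso_truth[f"delta_psi_{r}"] = delta
        iso_truth[f"class_{r}"] = [
            trajectory_class(bool(pn), bool(pr), float(d), thr)
            for pn, pr, d in zip(nr_present, r_present, delta)
        ]

    return SimulatedDataset(
        counts=counts,
        metadata=metadata,
        tree_newick=newick,
        true_psi=true_psi,
        gene_truth=gene_truth,
        iso_truth=iso_truth,
        species_table=species_table,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# reduced two-guild PSI experiment (for differential-splicing calibration)


def simulate_psi_experiment(
    n_genes: int = 1000,
    n_iso: int = 2,
    n_per_guild: int = 5,
    depth_mean: float = 200.0,
    delta_psi: float = 0.0,
    frac_ds: float = 0.0,
    nb_dispersion: float = 0.1,
    replicate_logit_sd: float = 0.2,
    base_concentration: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Two-guild PSI experiment with optional planted usage shifts.

    One herbivorous and one carnivorous species, ``n_per_guild`` replicates
    each, one tissue.  The first ``round(frac_ds * n_genes)`` genes carry a
    planted PSI difference of ``delta_psi`` on their least-used isoform
    (higher in herbivores).  Replicate counts: gene count ~ NegBin around
    ``depth_mean``; isoform counts multinomial around logit-jittered
    proportions.  Returns (psi, iso2gene, metadata).
    """
    rng = np.random.default_rng(seed)
    n_ds = round(frac_ds * n_genes)
    samples = [f"H_{i+1}" for i in range(n_per_guild)] + [
        f"C_{i+1}" for i in range(n_per_guild)
    ]
    guild_of = ["herbivore"] * n_per_guild + ["carnivore"] * n_per_guild

    iso_ids, gene_of, psi_rows = [], [], []
    for g in range(n_genes):
        base = rng.dirichlet(np.full(n_iso, base_concentration))
        focal = int(np.argmin(base))
        herb = _shift_focal(base, delta_psi, focal) if g < n_ds else base
        psi_block = np.full((n_iso, len(samples)), np.nan)
        for s, guild in enumerate(guild_of):
            p = _logit_jitter(
                herb if guild == "herbivore" else base, replicate_logit_sd, rng
            )
            r = 1.0 / nb_dispersion
            total = rng.negative_binomial(r, r / (r + depth_mean))
            if total > 0:
                iso_counts = rng.multinomial(total, p)
                psi_block[:, s] = iso_counts / total
        gid = f"g{g:05d}"
        for j in range(n_iso):
            iso_ids.append(f"{gid}_i{j+1}")
            gene_of.append(gid)
        psi_rows.append(psi_block)

    psi = pd.DataFrame(
        np.vstack(psi_rows), index=pd.Index(iso_ids, name="isoform_id"),
        columns=samples,
    )
    iso2gene = pd.Series(gene_of, index=psi.index, name="gene_id")
    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "species": ["SpH"] * n_per_guild + ["SpC"] * n_per_guild,
            "clade": "LV",
            "tissue": "OJ",
            "guild": guild_of,
            "replicate": list(range(1, n_per_guild + 1)) * 2,
        }
    ).set_index("sample_id", drop=False)
    return psi, iso2gene, metadata
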