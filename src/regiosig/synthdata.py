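"""Synthetic inputs for every stage of the pipeline.

This module generates, with known ground truth and full determinism under a
single seed per call:

* bulk RNA-seq count matrices in which a fraction of genes carries a
  region-specific (thalamus/cortex, or per-nucleus) program shared between
  neurons and astrocytes, expressed in astrocytes at an attenuated level;
* single-cell count matrices with per-cell UMI totals and a mitochondrial
  gene block, so downstream QC thresholds are exercised on both sides;
* tables of combinatorially barcoded cells (6 fluorophores x
  cytoplasmic/nuclear localization = 12 reporter channels) with a known
  clone partition, home thalamic nucleus per clone, and NeuN typing;
* ChIP-qPCR and RT-qPCR Ct tables realizing known percent-input enrichments
  and expression differences relative to Gapdh.

Counts are negative binomial with mean ``depth_j * baseline_i * 2**effect``
and dispersion ``alpha`` (variance ``mu + alpha * mu**2``); ``alpha = 0``
degenerates to Poisson.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import ConfigError, CountMatrix, NUCLEI
from .dists import DistSpec

__all__ = [
    "ExpressionSimConfig",
    "CloneSimConfig",
    "CtSimConfig",
    "GroundTruth",
    "simulate_bulk_counts",
    "simulate_sc_counts",
    "simulate_clones",
    "simulate_ct_tables",
    "analytic_code_collision_prob",
    "CHANNEL_NAMES",
]

_FLUOROPHORES = ("EGFP", "mCherry", "mKO", "mTSapphire", "mCerulean", "EYFP")
#: Fixed 12-channel order: each fluorophore in cytoplasmic then nuclear
#: (H2B-fused) localization.
CHANNEL_NAMES = tuple(
    f"{fp}_{loc}" for fp in _FLUOROPHORES for loc in ("cyt", "nuc")
)

_CELLTYPE_NAMES = ("astrocyte", "neuron")


def _region_names(n_regions: int) -> tuple:
    if n_regions == 2:
        return ("Th", "Ctx")
    if n_regions == 3:
        return NUCLEI
    return tuple(f"region{i + 1}" for i in range(n_regions))


def _celltype_names(n_celltypes: int) -> tuple:
    if n_celltypes <= 2:
        return _CELLTYPE_NAMES[:n_celltypes]
    return _CELLTYPE_NAMES + tuple(
        f"celltype{i + 1}" for i in range(2, n_celltypes)
    )


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Design of a simulated expression study.

    ``frac_region_genes`` of the genes carry a region program (split evenly
    across regions, log2 effect ``region_lfc`` in that region's samples).
    Region effects appear in neurons at full strength; in astrocytes a
    fraction ``astro_shared_frac`` of each program is expressed at
    ``astro_attenuation * region_lfc``, and a fraction ``astro_cross_frac``
    of each program leaks into astrocytes of every *other* region at the
    same attenuated level. ``frac_celltype_genes`` carry a cell-type-only
    effect of ``celltype_lfc``. The three ground-truth index sets (region,
    cell type, null) are disjoint.
    """

    n_genes: int = 5000
    n_regions: int = 2
    n_celltypes: int = 2
    samples_per_group: int = 4
    frac_region_genes: float = 0.15
    frac_celltype_genes: float = 0.10
    region_lfc: float = 1.5
    astro_attenuation: float = 0.5
    astro_shared_frac: float = 1.0
    astro_cross_frac: float = 0.0
    celltype_lfc: float = 2.0
    dispersion: float = 0.05
    lib_size_range: tuple = (5e5, 1.5e6)
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_genes >= 1, "n_genes", "must be >= 1")
        _require(self.n_regions >= 1, "n_regions", "must be >= 1")
        _require(self.n_celltypes >= 1, "n_celltypes", "must be >= 1")
        _require(self.samples_per_group >= 1, "samples_per_group", "must be >= 1")
        for name in ("frac_region_genes", "frac_celltype_genes",
                     "astro_shared_frac", "astro_cross_frac"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, "must lie in [0, 1]")
        _require(
            self.frac_region_genes + self.frac_celltype_genes <= 1.0,
            "frac_region_genes", "region + cell-type gene fractions exceed 1",
        )
        _require(0.0 < self.astro_attenuation <= 1.0, "astro_attenuation",
                 "must lie in (0, 1]")
        _require(self.dispersion >= 0.0, "dispersion", "must be >= 0")
        lo, hi = self.lib_size_range
        _require(0 < lo <= hi, "lib_size_range", "must be a positive (low, high) pair")

    @property
    def regions(self) -> tuple:
        return _region_names(self.n_regions)

    @property
    def celltypes(self) -> tuple:
        return _celltype_names(self.n_celltypes)


@dataclass
class GroundTruth:
    """True gene classes and effect sizes behind a simulated matrix.

    ``gene_class`` maps every gene to exactly one of ``region:<name>``,
    ``celltype:<name>`` or ``null``. ``effects`` is the full log2-effect
    matrix, genes x groups (one column per region/cell-type combination).
    """

    gene_class: pd.Series
    region_genes: dict
    celltype_genes: dict
    astro_shared: dict
    astro_cross: dict
    effects: pd.DataFrame
    config: ExpressionSimConfig

    def to_jsonable(self) -> dict:
        return {
            "gene_class": self.gene_class.to_dict(),
            "region_genes": {k: list(v) for k, v in self.region_genes.items()},
            "celltype_genes": {k: list(v) for k, v in self.celltype_genes.items()},
            "astro_shared": {k: list(v) for k, v in self.astro_shared.items()},
            "astro_cross": {
                k: {k2: list(v2) for k2, v2 in v.items()}
                for k, v in self.astro_cross.items()
            },
            "config": _config_dict(self.config),
        }


def _config_dict(cfg) -> dict:
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _gene_ids(n_genes: int, n_mito: int = 0) -> pd.Index:
    width = max(4, len(str(n_genes)))
    ids = [f"g{i:0{width}d}" for i in range(n_genes - n_mito)]
    ids += [f"mt-g{i:02d}" for i in range(n_mito)]
    return pd.Index(ids, name="gene")


def _assign_truth(cfg: ExpressionSimConfig, rng: np.random.Generator,
                  gene_ids: pd.Index, assignable: np.ndarray) -> GroundTruth:
    """Partition genes into region / cell-type / null classes and build the
    per-group log2 effect matrix. ``assignable`` marks genes eligible for an
    effect (the single-cell simulator excludes its mitochondrial block)."""
    regions, celltypes = cfg.regions, cfg.celltypes
    groups = [f"{r}|{c}" for r in regions for c in celltypes]
    n = len(gene_ids)

    n_region = int(round(cfg.frac_region_genes * n))
    n_celltype = int(round(cfg.frac_celltype_genes * n))
    pool = rng.permutation(np.flatnonzero(assignable))
    if n_region + n_celltype > len(pool):
        raise ConfigError("frac_region_genes: effect genes exceed assignable genes")
    region_idx = pool[:n_region]
    celltype_idx = pool[n_region:n_region + n_celltype]

    gene_class = pd.Series("null", index=gene_ids, name="gene_class")
    effects = pd.DataFrame(0.0, index=gene_ids, columns=groups)

    region_genes: dict = {r: [] for r in regions}
    astro_shared: dict = {r: [] for r in regions}
    astro_cross: dict = {r: {r2: [] for r2 in regions if r2 != r} for r in regions}
    per_region = np.array_split(region_idx, cfg.n_regions) if cfg.n_regions else []
    for r, idx in zip(regions, per_region):
        ids = list(gene_ids[np.sort(idx)])
        region_genes[r] = ids
        gene_class.loc[ids] = f"region:{r}"
        for c in celltypes:
            if c != "astrocyte":
                effects.loc[ids, f"{r}|{c}"] += cfg.region_lfc
        if "astrocyte" in celltypes:
            n_shared = int(round(cfg.astro_shared_frac * len(ids)))
            shared = list(rng.permutation(ids)[:n_shared])
            astro_shared[r] = sorted(shared)
            effects.loc[shared, f"{r}|astrocyte"] += (
                cfg.astro_attenuation * cfg.region_lfc
            )
            for r2 in regions:
                if r2 == r:
                    continue
                n_cross = int(round(cfg.astro_cross_frac * len(ids)))
                cross = list(rng.permutation(ids)[:n_cross])
                astro_cross[r][r2] = sorted(cross)
                effects.loc[cross, f"{r2}|astrocyte"] += (
                    cfg.astro_attenuation * cfg.region_lfc
                )

    celltype_genes: dict = {c: [] for c in celltypes}
    per_type = np.array_split(celltype_idx, cfg.n_celltypes) if cfg.n_celltypes else []
    for c, idx in zip(celltypes, per_type):
        ids = list(gene_ids[np.sort(idx)])
        celltype_genes[c] = ids
        gene_class.loc[ids] = f"celltype:{c}"
        for r in regions:
            effects.loc[ids, f"{r}|{c}"] += cfg.celltype_lfc

    return GroundTruth(
        gene_class=gene_class,
        region_genes=region_genes,
        celltype_genes=celltype_genes,
        astro_shared=astro_shared,
        astro_cross=astro_cross,
        effects=effects,
        config=cfg,
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0.0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


def simulate_bulk_counts(cfg: ExpressionSimConfig):
    """Simulate a bulk count matrix with its :class:`GroundTruth`.

    Counts are NB(mean = depth_j * baseline_i * 2**effect, dispersion
    alpha); per-sample depths are uniform in ``lib_size_range`` so
    size-factor recovery is a meaningful downstream test. Deterministic
    given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gene_ids = _gene_ids(cfg.n_genes)
    truth = _assign_truth(cfg, rng, gene_ids, np.ones(cfg.n_genes, dtype=bool))

    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    baseline /= baseline.sum()

    rows = []
    for r in cfg.regions:
        for c in cfg.celltypes:
            for k in range(cfg.samples_per_group):
                rows.append((f"{r}_{c}_{k + 1}", r, c, f"animal{k + 1}"))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "region", "cell_type", "animal"]
    ).set_index("sample_id")
    samples["nucleus"] = samples["region"].where(
        samples["region"].isin(NUCLEI), other=pd.NA
    )

    lo, hi = cfg.lib_size_range
    depths = rng.uniform(lo, hi, size=len(samples))
    group_of = samples["region"] + "|" + samples["cell_type"]
    eff = truth.effects[group_of.to_numpy()].to_numpy()  # genes x samples
    mu = depths[None, :] * baseline[:, None] * np.exp2(eff)
    counts = _nb_draw(rng, mu, cfg.dispersion)

    return CountMatrix(counts=counts, gene_ids=gene_ids, samples=samples), truth


def simulate_sc_counts(
    cfg: ExpressionSimConfig,
    n_cells_per_group: int,
    mito_frac_law=None,
    umi_law=None,
    n_mito_genes: int = 10,
    mito_policy: str = "resample",
):
    """Simulate a single-cell count matrix with per-cell metadata.

    Each cell draws its total UMI count from ``umi_law`` and its
    mitochondrial fraction from ``mito_frac_law``; a dedicated block of
    ``n_mito_genes`` genes (ids prefixed ``mt-``) receives a Binomial(total,
    fraction) share of the counts, the remainder is multinomial over the
    non-mitochondrial genes with the cell's group expression profile.
    Region and cell-type labels are attached directly (no clustering).

    ``mito_policy`` controls fraction draws outside [0, 1]: ``"resample"``
    redraws them, ``"error"`` raises.
    """
    cfg.validate()
    if n_cells_per_group < 1:
        raise ConfigError("n_cells_per_group: must be >= 1")
    if not 0 <= n_mito_genes < cfg.n_genes:
        raise ConfigError("n_mito_genes: must be in [0, n_genes)")
    if mito_policy not in ("resample", "error"):
        raise ConfigError("mito_policy: must be 'resample' or 'error'")
    umi_law = DistSpec.coerce(
        umi_law if umi_law is not None else {"name": "negbinom", "mean": 3000, "dispersion": 0.3}
    )
    mito_frac_law = DistSpec.coerce(
        mito_frac_law if mito_frac_law is not None else {"name": "beta", "a": 2.0, "b": 60.0}
    )

    rng = np.random.default_rng(cfg.seed)
    gene_ids = _gene_ids(cfg.n_genes, n_mito=n_mito_genes)
    assignable = np.ones(cfg.n_genes, dtype=bool)
    if n_mito_genes:
        assignable[-n_mito_genes:] = False
    truth = _assign_truth(cfg, rng, gene_ids, assignable)

    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    baseline /= baseline.sum()
    nonmito = np.flatnonzero(assignable)

    groups = [(r, c) for r in cfg.regions for c in cfg.celltypes]
    n_cells = n_cells_per_group * len(groups)

    totals = np.rint(umi_law.sample(rng, n_cells)).astype(int)
    if np.any(totals < 0):
        raise ConfigError("umi_law: produced negative totals")
    fracs = mito_frac_law.sample(rng, n_cells)
    bad = (fracs < 0) | (fracs > 1)
    if np.any(bad):
        if mito_policy == "error":
            raise ConfigError("mito_frac_law: fraction outside [0, 1]")
        for _ in range(1000):
            fracs[bad] = mito_frac_law.sample(rng, int(bad.sum()))
            bad = (fracs < 0) | (fracs > 1)
            if not np.any(bad):
                break
        else:
            raise ConfigError("mito_frac_law: could not resample into [0, 1]")

    counts = np.zeros((cfg.n_genes, n_cells), dtype=np.int64)
    meta_rows = []
    cell = 0
    for r, c in groups:
        eff = truth.effects[f"{r}|{c}"].to_numpy()
        probs = baseline * np.exp2(eff)
        p_nonmito = probs[nonmito] / probs[nonmito].sum()
        for _ in range(n_cells_per_group):
            total = totals[cell]
            m = rng.binomial(total, fracs[cell]) if (n_mito_genes and total > 0) else 0
            if n_mito_genes and m > 0:
                counts[-n_mito_genes:, cell] = rng.multinomial(
                    m, np.full(n_mito_genes, 1.0 / n_mito_genes)
                )
            if total - m > 0:
                counts[nonmito, cell] = rng.multinomial(total - m, p_nonmito)
            meta_rows.append(
                (
                    f"cell{cell:05d}", r, c, int(total),
                    (m / total) if total > 0 else 0.0,
                )
            )
            cell += 1

    cells = pd.DataFrame(
        meta_rows,
        columns=["cell_id", "region", "cell_type", "total_umis", "mito_fraction"],
    ).set_index("cell_id")
    cells["nucleus"] = cells["region"].where(cells["region"].isin(NUCLEI), other=pd.NA)
    cells["animal"] = "animal1"

    return CountMatrix(counts=counts, gene_ids=gene_ids, samples=cells), truth


@dataclass(frozen=True)
class CloneSimConfig:
    """Design of a simulated combinatorial-labeling (StarTrack-like) cohort.

    Each progenitor independently integrates each of ``n_channels`` reporter
    constructs with probability ``p_integrate`` (all-zero codes are redrawn:
    unlabeled progenitors are invisible). Identical codes in distinct
    progenitors are *not* prevented; collisions are a modeled error source.
    Cells inherit the code, stay in the clone's home nucleus with
    probability ``1 - dispersion_eps``, and are typed NeuN+/- according to
    the clone's composition (a ``frac_pure_clones`` share of clones is
    single-type).
    """

    n_progenitors: int = 50
    p_integrate: float = 0.5
    n_channels: int = 12
    clone_size_law: object = None
    home_nucleus_probs: tuple = (0.18, 0.56, 0.26)
    dispersion_eps: float = 0.15
    p_neuron: float = 0.5
    frac_pure_clones: float = 0.39
    n_animals: int = 1
    emit_intensities: bool = False
    intensity_on: tuple = (4.0, 0.25)
    intensity_off: tuple = (1.0, 0.25)
    seed: int = 0

    def size_law(self) -> DistSpec:
        law = self.clone_size_law
        if law is None:
            law = {"name": "poisson", "lam": 8.0}
        return DistSpec.coerce(law)

    def validate(self) -> None:
        _require(self.n_progenitors >= 1, "n_progenitors", "must be >= 1")
        _require(0.0 < self.p_integrate <= 1.0, "p_integrate",
                 "must be in (0, 1]; 0 leaves no labelable progenitors")
        _require(self.n_channels >= 1, "n_channels", "must be >= 1")
        probs = np.asarray(self.home_nucleus_probs, dtype=float)
        _require(len(probs) == len(NUCLEI), "home_nucleus_probs",
                 f"needs one entry per nucleus {NUCLEI}")
        _require(np.all((probs >= 0) & (probs <= 1)), "home_nucleus_probs",
                 "entries must lie in [0, 1]")
        _require(abs(probs.sum() - 1.0) <= 1e-12, "home_nucleus_probs",
                 "must sum to 1 within 1e-12")
        _require(0.0 <= self.dispersion_eps <= 1.0, "dispersion_eps",
                 "must lie in [0, 1]")
        _require(0.0 <= self.p_neuron <= 1.0, "p_neuron", "must lie in [0, 1]")
        _require(0.0 <= self.frac_pure_clones <= 1.0, "frac_pure_clones",
                 "must lie in [0, 1]")
        _require(self.n_animals >= 1, "n_animals", "must be >= 1")
        self.size_law()


def analytic_code_collision_prob(p_integrate: float, n_channels: int = 12) -> float:
    """Probability that two independent progenitors draw the same code.

    Codes are ``n_channels`` Bernoulli(p) bits conditioned on not being
    all-zero, so the pairwise collision probability is the sum of squared
    code probabilities::

        [ (p^2 + (1-p)^2)^k - (1-p)^(2k) ] / [ 1 - (1-p)^k ]^2
    """
    p, k = p_integrate, n_channels
    q = 1.0 - p
    denom = 1.0 - q**k
    if denom <= 0:
        raise ConfigError("p_integrate: no labelable codes")
    return ((p * p + q * q) ** k - q ** (2 * k)) / denom**2


def simulate_clones(cfg: CloneSimConfig) -> pd.DataFrame:
    """Simulate a barcoded cell table with ground-truth progenitor ids.

    Returns a DataFrame with one row per cell: ``animal_id``, ``cell_id``,
    ``progenitor_id`` (ground truth), ``nucleus``, ``neun``, and the 12
    boolean reporter channels (plus ``<channel>_intensity`` columns when
    ``emit_intensities`` is set).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    size_law = cfg.size_law()
    probs = np.asarray(cfg.home_nucleus_probs, dtype=float)

    channel_cols = list(CHANNEL_NAMES[: cfg.n_channels])
    if cfg.n_channels > len(CHANNEL_NAMES):
        channel_cols += [f"ch{i}" for i in range(len(CHANNEL_NAMES), cfg.n_channels)]

    rows = []
    for prog in range(cfg.n_progenitors):
        code = rng.random(cfg.n_channels) < cfg.p_integrate
        while not code.any():
            code = rng.random(cfg.n_channels) < cfg.p_integrate
        animal = f"animal{prog % cfg.n_animals + 1}"
        home = int(rng.choice(len(NUCLEI), p=probs))
        size = max(1, int(round(size_law.sample(rng, 1)[0])))

        pure = rng.random() < cfg.frac_pure_clones
        if pure:
            neun = np.full(size, rng.random() < cfg.p_neuron)
        else:
            neun = rng.random(size) < cfg.p_neuron
            # a "mixed" lineage must actually contain both types when it can
            tries = 0
            while size >= 2 and len(set(neun)) == 1 and tries < 1000:
                neun = rng.random(size) < cfg.p_neuron
                tries += 1

        for j in range(size):
            if rng.random() < cfg.dispersion_eps:
                others = [i for i in range(len(NUCLEI)) if i != home]
                w = probs[others]
                w = w / w.sum() if w.sum() > 0 else np.full(len(others), 1 / len(others))
                nuc = int(rng.choice(others, p=w))
            else:
                nuc = home
            rows.append(
                {
                    "animal_id": animal,
                    "cell_id": f"{animal}_p{prog:03d}_c{j:03d}",
                    "progenitor_id": f"p{prog:03d}",
                    "nucleus": NUCLEI[nuc],
                    "neun": bool(neun[j]),
                    **{ch: bool(b) for ch, b in zip(channel_cols, code)},
                }
            )

    cells = pd.DataFrame(rows)
    if cfg.emit_intensities:
        on_mu, on_sd = cfg.intensity_on
        off_mu, off_sd = cfg.intensity_off
        for ch in channel_cols:
            bits = cells[ch].to_numpy()
            mu = np.where(bits, on_mu, off_mu)
            sd = np.where(bits, on_sd, off_sd)
            cells[f"{ch}_intensity"] = np.exp(rng.normal(mu, sd))
    return cells


@dataclass(frozen=True)
class CtSimConfig:
    """Known enrichments and expression differences behind simulated qPCR.

    ``true_percent_input`` maps gene -> (H3K4me3 %, H3K27me3 %). IP Cts are
    generated from the percent-input identity
    ``ct_ip = ct_input - log2(true_pi / (100 * input_dilution)) + noise`` so
    the downstream percent-input computation inverts the simulator exactly
    at zero noise. ``expression_dct`` maps gene -> delta-Ct versus Gapdh.
    """

    true_percent_input: dict = field(default_factory=dict)
    input_dilution: float = 0.01
    ct_noise_sd: float = 0.0
    gapdh_ct: float = 18.0
    expression_dct: dict = field(default_factory=dict)
    input_ct: float = 22.0
    igg_percent_input: float = 0.05
    n_replicates: int = 12
    gene_regions: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        _require(0.0 < self.input_dilution <= 1.0, "input_dilution",
                 "must lie in (0, 1]")
        _require(self.ct_noise_sd >= 0.0, "ct_noise_sd", "must be >= 0")
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _require(self.igg_percent_input > 0, "igg_percent_input", "must be > 0")
        for gene, (k4, k27) in self.true_percent_input.items():
            _require(k4 > 0 and k27 > 0, "true_percent_input",
                     f"values for {gene!r} must be > 0")


def simulate_ct_tables(cfg: CtSimConfig):
    """Simulate ChIP-qPCR and RT-qPCR Ct tables.

    Returns ``(chip, rt)``: ``chip`` has one row per gene x mark x replicate
    with columns ``gene, region, mark, replicate, ct`` (marks: H3K4me3,
    H3K27me3, IgG, input); ``rt`` has ``gene, replicate, ct_gene, ct_ref``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    adj = math.log2(1.0 / cfg.input_dilution)

    def noisy(x: float) -> float:
        return x + (rng.normal(0.0, cfg.ct_noise_sd) if cfg.ct_noise_sd > 0 else 0.0)

    chip_rows = []
    for gene, (k4, k27) in cfg.true_percent_input.items():
        region = cfg.gene_regions.get(gene, "NA")
        for rep in range(1, cfg.n_replicates + 1):
            ct_input = noisy(cfg.input_ct)
            for mark, pi in (
                ("H3K4me3", k4),
                ("H3K27me3", k27),
                ("IgG", cfg.igg_percent_input),
            ):
                # inverse of the percent-input formula at the true enrichment
                ct_ip = noisy(cfg.input_ct - (math.log2(pi / 100.0) + adj))
                chip_rows.append((gene, region, mark, rep, ct_ip))
            chip_rows.append((gene, region, "input", rep, ct_input))
    chip = pd.DataFrame(chip_rows, columns=["gene", "region", "mark", "replicate", "ct"])

    rt_rows = []
    for gene, dct in cfg.expression_dct.items():
        for rep in range(1, cfg.n_replicates + 1):
            rt_rows.append((gene, rep, noisy(cfg.gapdh_ct + dct), noisy(cfg.gapdh_ct)))
    rt = pd.DataFrame(rt_rows, columns=["gene", "replicate", "ct_gene", "ct_ref"])
    return chip, rt
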