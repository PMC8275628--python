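"""Synthetic ploidy-resolved liver snRNA-seq data with known ground truth.

The generator emulates the statistical structure a deep plate-based
single-nucleus experiment on FACS-gated liver nuclei produces, so that every
pipeline stage can be exercised against planted truth:

- negative-binomial endogenous counts with per-nucleus lognormal capture
  efficiency and per-ploidy dispersion (diploid nuclei more dispersed);
- a global detection increase in 4n nuclei, calibrated in closed form from
  the NB detection probability so the expected detected-gene fold equals the
  configured value (1.25 by default);
- ERCC spike-ins (92 species spanning a ~2^20 concentration range) drawn as
  Poisson counts at one of two dilutions assigned by plate;
- a latent lobule coordinate z in [0, 1] per hepatocyte driving opposite
  exponential pericentral/periportal expression gradients, with 4n nuclei
  preferentially placed pericentrally (planted enrichment);
- a planted differentially expressed gene set between 2n and 4n;
- a correlated binary stem/progenitor marker module driven by a shared
  latent Bernoulli factor;
- six liver cell types separated by boosted marker and program genes.

Everything is bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from hepatoseq.containers import CountMatrix

CELL_TYPES = ("hepatocyte", "hepatobiliary", "endothelial", "apc", "lymphocyte", "stellate")

CELLTYPE_MARKERS: dict[str, list[str]] = {
    "hepatocyte": ["Cyp27a1", "Ppara", "Pck1"],
    "hepatobiliary": ["Sspn", "Cmss1", "Epcam"],
    "endothelial": ["Plekhg1", "Stab2", "Ptprb"],
    "apc": ["Clec4f", "Cd5l", "Slc40a1"],
    "lymphocyte": ["Bcl2", "Skap1", "Gata3"],
    "stellate": ["Reln", "Ecm1", "Ldb2"],
}

ZONATION_PANEL = {
    "pericentral": ["Cyp2e1", "Gsta3", "Cyp27a1", "Mup17"],
    "periportal": ["Alb", "Cyp2f2", "Asl", "Gls2"],
    "non_zonated": ["Hnf4a", "Ces3a", "Hamp", "Cyp3a25"],
}

STEM_MARKERS = ["Icam1", "Afp", "Sox9", "Epcam", "Axin2", "Tbx3", "Itga6", "Tert", "Lgr5", "Notch2"]
STEM_MODULE = ["Axin2", "Tbx3", "Lgr5", "Itga6", "Tert", "Notch2"]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset (defaults mirror the
    magnitudes reported for the real experiment, at a desk-scale problem
    size of ~1,200 nuclei x 3,000 genes)."""

    seed: int
    # population sizes
    n_hepatocytes_2n: int = 400
    n_hepatocytes_4n: int = 400
    n_other: dict = field(
        default_factory=lambda: {
            "hepatobiliary": 100,
            "endothelial": 80,
            "apc": 60,
            "lymphocyte": 100,
            "stellate": 60,
        }
    )
    n_genes: int = 3000
    # negative binomial dispersion (size parameter theta); diploid nuclei are
    # 1.5x more dispersed than tetraploid ones
    theta_4n: float = 2.0
    theta_2n_ratio: float = 1.5
    theta_other: float = 2.0
    # per-nucleus capture efficiency ~ LogNormal(0, sigma)
    efficiency_sigma: float = 0.3
    # expected detected-gene fold in 4n vs 2n hepatocytes
    detection_fold_4n: float = 1.25
    # base gene mean distribution ~ LogNormal(log(1.5), 1.8) counts
    gene_mean_loc: float = math.log(1.5)
    gene_mean_scale: float = 1.8
    # cell-type structure
    marker_boost: float = 8.0
    n_program_genes: int = 60
    program_boost: float = 6.0
    # zonation
    n_pericentral: int = 120
    n_periportal: int = 80
    n_cv_only_4n: int = 15
    n_pv_only_2n: int = 8
    slope_min: float = 1.0
    slope_max: float = 2.5
    panel_slope: float = 2.5
    panel_mean_min: float = 80.0
    panel_mean_max: float = 300.0
    # 4n pericentral placement: 2n lobule coordinates are uniform while the 4n
    # density is planted_enrichment_4n times the 2n density everywhere below
    # z = enrichment_cut, so any pericentral boundary at or below the cut
    # recovers the planted enrichment exactly
    planted_enrichment_4n: float = 1.3
    enrichment_cut: float = 0.7
    # cell-type marker genes draw their base mean from this window so they are
    # reliably detectable (a marker lost to the gene filter cannot annotate)
    marker_mean_min: float = 3.0
    marker_mean_max: float = 10.0
    # planted effects (DEG, zonation, programs) go on genes at least this
    # expressed: an effect planted on a gene that cannot pass the QC gene
    # filter is unrecoverable by construction
    plant_min_base_mean: float = 0.5
    # planted DEG set (2n vs 4n)
    n_deg_up: int = 40
    n_deg_down: int = 20
    deg_log2fc: float = 2.0
    # stem marker module (binary co-detection structure in hepatocytes)
    p_latent: float = 0.6
    p_detect_in_module: float = 0.8
    p_detect_out_module: float = 0.05
    p_detect_background: float = 0.15
    stem_mean_count: float = 6.0
    # ERCC spike-ins
    n_ercc: int = 92
    ercc_total_by_dilution: dict = field(
        default_factory=lambda: {"1:100000": 18000.0, "1:300000": 6000.0}
    )
    # plate layout
    n_plates: int = 4
    n_animals: int = 2
    n_technical_replicates: int = 2
    gene_length_loc: float = math.log(1.5)  # kb
    gene_length_scale: float = 0.6

    @property
    def theta_2n(self) -> float:
        return self.theta_4n / self.theta_2n_ratio

    @property
    def planted_enrichment(self) -> float:
        return self.planted_enrichment_4n

    @property
    def pericentral_fraction_4n(self) -> float:
        """P(z < 0.5) for a 4n nucleus under the planted density."""
        return self.planted_enrichment_4n * 0.5

    def validate(self) -> None:
        planted = (
            self.n_pericentral + self.n_periportal + self.n_cv_only_4n + self.n_pv_only_2n
            + self.n_deg_up + self.n_deg_down + len(CELL_TYPES) * self.n_program_genes
        )
        named = len(_named_genes())
        if planted + named > self.n_genes:
            raise ValueError(
                f"config plants {planted + named} special genes but only {self.n_genes} genes exist"
            )
        if not 0 < self.enrichment_cut <= 1:
            raise ValueError("enrichment_cut must be in (0, 1]")
        if not 0 < self.planted_enrichment_4n * self.enrichment_cut <= 1:
            raise ValueError(
                "planted_enrichment_4n * enrichment_cut must be in (0, 1] for a valid density"
            )
        for p in (self.p_latent, self.p_detect_in_module, self.p_detect_out_module, self.p_detect_background):
            if not 0 <= p <= 1:
                raise ValueError("stem detection probabilities must be in [0, 1]")
        if set(self.ercc_total_by_dilution) != {"1:100000", "1:300000"}:
            raise ValueError("expected exactly the two study dilution groups")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside the count matrix."""

    nuclei: pd.DataFrame  # z, cell_type, ploidy, efficiency
    genes: pd.DataFrame   # base_mean, zonation_class, slope, deg, stem_marker, stem_module
    planted_enrichment: float
    detection_scale_4n: float
    detection_fold: float


def _named_genes() -> list[str]:
    seen: dict[str, None] = {}
    for genes in CELLTYPE_MARKERS.values():
        for g in genes:
            seen.setdefault(g)
    for genes in ZONATION_PANEL.values():
        for g in genes:
            seen.setdefault(g)
    for g in STEM_MARKERS:
        seen.setdefault(g)
    return list(seen)


def ercc_concentration_table(n_species: int = 92) -> pd.DataFrame:
    """Synthetic ERCC spike-in concentration table.

    A stand-in for the commercial 92-species mix: relative molar
    concentrations are log2-spaced over a 2^20 dynamic range, matching the
    real mix's span.  Only relative abundances matter for size factors.
    """
    ids = [f"ERCC-{i:05d}" for i in range(1, n_species + 1)]
    conc = 2.0 ** np.linspace(0.0, 20.0, n_species)
    return pd.DataFrame({"relative_concentration": conc / conc.sum()}, index=pd.Index(ids, name="feature_id"))


def _nb_detection_prob(mu: np.ndarray, theta: float) -> np.ndarray:
    """P(NB(mu, theta) > 0) = 1 - (theta / (theta + mu))^theta."""
    mu = np.asarray(mu, dtype=float)
    return 1.0 - (theta / (theta + mu)) ** theta


def _solve_detection_scale(
    mu_2n: np.ndarray, theta_2n: float, theta_4n: float, fold: float, const: float = 0.0
) -> float:
    """Global 4n mean multiplier s with E[detected | 4n] = fold * E[detected | 2n].

    ``const`` adds ploidy-independent expected detections (the stem markers,
    which follow their own Bernoulli model) to both sides.
    """
    target = fold * (_nb_detection_prob(mu_2n, theta_2n).sum() + const)

    def gap(s: float) -> float:
        return _nb_detection_prob(s * mu_2n, theta_4n).sum() + const - target

    return float(scipy.optimize.brentq(gap, 1e-3, 1e3, xtol=1e-10))


def _zonation_factor(z: np.ndarray, slope: float, kind: str) -> np.ndarray:
    """Mean multiplier along the lobule coordinate, centred at z = 0.5.

    Pericentral genes decay CV -> PV (high at z = 0); periportal genes rise.
    """
    if kind == "cv":
        return np.exp(-slope * (z - 0.5))
    if kind == "pv":
        return np.exp(slope * (z - 0.5))
    raise ValueError(kind)


def _sample_z(rng: np.random.Generator, n: int, enrichment: float, cut: float) -> np.ndarray:
    """Lobule coordinate whose density is ``enrichment`` x uniform below ``cut``.

    Below the cut the density ratio against the uniform 2n coordinate is a
    constant ``enrichment``, so the cumulative ratio P_4n(z < t) / P_2n(z < t)
    equals the planted enrichment exactly for every boundary t <= cut; the
    compensating mass deficit sits in the far periportal tail.
    """
    low = rng.random(n) < enrichment * cut
    z = np.empty(n)
    z[low] = rng.uniform(0.0, cut, low.sum())
    z[~low] = rng.uniform(cut, 1.0, (~low).sum())
    return z


def simulate_dataset(cfg: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Generate a count matrix plus ground truth under the configured conditions."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # ---- gene universe -----------------------------------------------------
    named = _named_genes()
    n_anon = cfg.n_genes - len(named)
    gene_names = named + [f"Gene{i:05d}" for i in range(1, n_anon + 1)]
    genes = pd.DataFrame(index=pd.Index(gene_names, name="feature_id"))
    genes["gene_name"] = gene_names
    genes["base_mean"] = rng.lognormal(cfg.gene_mean_loc, cfg.gene_mean_scale, cfg.n_genes)
    genes["zonation_class"] = "none"
    genes["slope"] = 0.0
    genes["deg"] = "none"
    genes["stem_marker"] = genes.index.isin(STEM_MARKERS)
    genes["stem_module"] = genes.index.isin(STEM_MODULE)

    # detectability floor for cell-type markers (zonation panel overrides below)
    all_markers = sorted({g for gs in CELLTYPE_MARKERS.values() for g in gs})
    genes.loc[all_markers, "base_mean"] = rng.uniform(
        cfg.marker_mean_min, cfg.marker_mean_max, len(all_markers)
    )

    # well-expressed zonation panel genes with a strong common slope
    for kind, panel_genes in (("cv", ZONATION_PANEL["pericentral"]), ("pv", ZONATION_PANEL["periportal"])):
        genes.loc[panel_genes, "base_mean"] = rng.uniform(cfg.panel_mean_min, cfg.panel_mean_max, len(panel_genes))
        genes.loc[panel_genes, "zonation_class"] = kind
        genes.loc[panel_genes, "slope"] = cfg.panel_slope
    genes.loc[ZONATION_PANEL["non_zonated"], "base_mean"] = rng.uniform(
        cfg.panel_mean_min, cfg.panel_mean_max, len(ZONATION_PANEL["non_zonated"])
    )

    # anonymous planted gene classes, drawn disjointly from detectable genes
    anon_pool = [
        g
        for g in gene_names
        if g.startswith("Gene") and genes.at[g, "base_mean"] >= cfg.plant_min_base_mean
    ]
    rng.shuffle(anon_pool)
    needed = (
        cfg.n_pericentral + cfg.n_periportal + cfg.n_cv_only_4n + cfg.n_pv_only_2n
        + cfg.n_deg_up + cfg.n_deg_down + len(CELL_TYPES) * cfg.n_program_genes
    )
    if len(anon_pool) < needed:
        raise ValueError(
            f"only {len(anon_pool)} genes clear plant_min_base_mean but {needed} plants requested"
        )
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = anon_pool[cursor : cursor + n]
        cursor += n
        return out

    for cls, n_cls in (
        ("cv", cfg.n_pericentral),
        ("pv", cfg.n_periportal),
        ("cv_only_4n", cfg.n_cv_only_4n),
        ("pv_only_2n", cfg.n_pv_only_2n),
    ):
        chosen = take(n_cls)
        genes.loc[chosen, "zonation_class"] = cls
        genes.loc[chosen, "slope"] = rng.uniform(cfg.slope_min, cfg.slope_max, n_cls)
    genes.loc[take(cfg.n_deg_up), "deg"] = "up"
    genes.loc[take(cfg.n_deg_down), "deg"] = "down"
    program_genes = {t: take(cfg.n_program_genes) for t in CELL_TYPES}

    genes["length_kb"] = rng.lognormal(cfg.gene_length_loc, cfg.gene_length_scale, cfg.n_genes)

    # ---- nucleus table -----------------------------------------------------
    blocks: list[tuple[str, str, int]] = [
        ("hepatocyte", "2n", cfg.n_hepatocytes_2n),
        ("hepatocyte", "4n", cfg.n_hepatocytes_4n),
    ] + [(t, "2n", n) for t, n in cfg.n_other.items()]
    cell_type = np.concatenate([[t] * n for t, _, n in blocks])
    ploidy = np.concatenate([[p] * n for _, p, n in blocks])
    n_nuclei = len(cell_type)
    plates = np.concatenate([[f"P{i % cfg.n_plates + 1}" for i in range(n)] for _, _, n in blocks])
    animals = np.array([f"A{(int(p[1:]) - 1) % cfg.n_animals + 1}" for p in plates])
    dilution = np.where(np.isin(plates, ["P1", "P2"]), "1:100000", "1:300000")
    efficiency = rng.lognormal(0.0, cfg.efficiency_sigma, n_nuclei)

    z = np.full(n_nuclei, np.nan)
    hep = cell_type == "hepatocyte"
    is_4n = ploidy == "4n"
    z[hep & ~is_4n] = rng.uniform(0.0, 1.0, (hep & ~is_4n).sum())
    z[hep & is_4n] = _sample_z(
        rng, (hep & is_4n).sum(), cfg.planted_enrichment_4n, cfg.enrichment_cut
    )

    # ---- detection-fold calibration ---------------------------------------
    stem_mask = genes["stem_marker"].to_numpy()
    mu_hep_2n = genes["base_mean"].to_numpy().copy()
    for kind in ("cv", "pv"):
        sel = (genes["zonation_class"] == kind).to_numpy()
        s = genes.loc[sel, "slope"].to_numpy()
        # average gradient factor over z ~ U(0, 1): 2 sinh(s/2) / s
        mu_hep_2n[sel] *= 2.0 * np.sinh(s / 2.0) / s
    hep_markers = CELLTYPE_MARKERS["hepatocyte"]
    mu_hep_2n[genes.index.get_indexer(hep_markers)] *= cfg.marker_boost
    mu_hep_2n[genes.index.get_indexer(program_genes["hepatocyte"])] *= cfg.program_boost
    p_stem = np.where(
        genes.loc[stem_mask].index.isin(STEM_MODULE),
        cfg.p_latent * cfg.p_detect_in_module + (1 - cfg.p_latent) * cfg.p_detect_out_module,
        cfg.p_detect_background,
    ).sum()
    s4 = _solve_detection_scale(
        mu_hep_2n[~stem_mask], cfg.theta_2n, cfg.theta_4n, cfg.detection_fold_4n, const=p_stem
    )

    # ---- endogenous mean matrix -------------------------------------------
    base = genes["base_mean"].to_numpy()
    mu = np.tile(base, (n_nuclei, 1))
    for t in CELL_TYPES:
        rows = cell_type == t
        mu[np.ix_(rows, genes.index.get_indexer(CELLTYPE_MARKERS[t]))] *= cfg.marker_boost
        mu[np.ix_(rows, genes.index.get_indexer(program_genes[t]))] *= cfg.program_boost

    slope = genes["slope"].to_numpy()
    zclass = genes["zonation_class"].to_numpy()
    hep_idx = np.where(hep)[0]
    z_hep = z[hep_idx]
    hep_4n = is_4n[hep_idx]
    for kind, only in (("cv", None), ("pv", None), ("cv_only_4n", "4n"), ("pv_only_2n", "2n")):
        cols = np.where(zclass == kind)[0]
        if not len(cols):
            continue
        base_kind = kind.split("_")[0]
        sign = -1.0 if base_kind == "cv" else 1.0
        factors = np.exp(np.outer(sign * (z_hep - 0.5), slope[cols]))
        if only == "4n":
            factors[~hep_4n] = 1.0
        elif only == "2n":
            factors[hep_4n] = 1.0
        mu[np.ix_(hep_idx, cols)] *= factors

    deg = genes["deg"].to_numpy()
    rows_4n = np.where(hep & is_4n)[0]
    mu[np.ix_(rows_4n, np.where(deg == "up")[0])] *= 2.0**cfg.deg_log2fc
    mu[np.ix_(rows_4n, np.where(deg == "down")[0])] *= 2.0**-cfg.deg_log2fc
    mu[rows_4n] *= s4
    mu *= efficiency[:, None]

    # ---- sample endogenous counts -----------------------------------------
    theta = np.where(
        cell_type == "hepatocyte", np.where(is_4n, cfg.theta_4n, cfg.theta_2n), cfg.theta_other
    )
    counts = np.empty((n_nuclei, cfg.n_genes), dtype=np.int64)
    for th in np.unique(theta):
        rows = np.where(theta == th)[0]
        lam = rng.gamma(shape=th, scale=mu[rows] / th)
        counts[rows] = rng.poisson(lam)

    # stem markers in hepatocytes follow the shared latent Bernoulli module
    stem_cols = np.where(stem_mask)[0]
    stem_names = genes.index[stem_cols]
    latent = rng.random(len(hep_idx)) < cfg.p_latent
    # detected stem transcripts scale with capture efficiency and the global
    # 4n transcription increase like every other endogenous transcript
    stem_scale = efficiency[hep_idx] * np.where(hep_4n, s4, 1.0)
    for col, name in zip(stem_cols, stem_names):
        if name in STEM_MODULE:
            p = np.where(latent, cfg.p_detect_in_module, cfg.p_detect_out_module)
        else:
            p = np.full(len(hep_idx), cfg.p_detect_background)
        detected = rng.random(len(hep_idx)) < p
        lam = max(cfg.stem_mean_count - 1.0, 0.0) * stem_scale
        counts[hep_idx, col] = detected * (1 + rng.poisson(lam))

    # ---- ERCC spike-ins ----------------------------------------------------
    conc = ercc_concentration_table(cfg.n_ercc)
    amp = np.array([cfg.ercc_total_by_dilution[d] for d in dilution])
    ercc_mu = np.outer(efficiency * amp, conc["relative_concentration"].to_numpy())
    ercc_counts = rng.poisson(ercc_mu)

    # ---- assemble tables ---------------------------------------------------
    nucleus_ids = [f"N{i + 1:04d}" for i in range(n_nuclei)]
    nuclei = pd.DataFrame(
        {
            "ploidy": pd.Categorical(ploidy, categories=["2n", "4n", "8n", "16n"]),
            "plate_id": plates,
            "animal_id": animals,
            "dilution_group": dilution,
            "is_technical_replicate": False,
        },
        index=pd.Index(nucleus_ids, name="nucleus_id"),
    )

    feature_table = pd.concat(
        [
            genes[["gene_name", "length_kb"]].assign(is_ercc=False),
            pd.DataFrame(
                {"gene_name": conc.index, "length_kb": 1.0, "is_ercc": True}, index=conc.index
            ),
        ]
    )[["gene_name", "is_ercc", "length_kb"]]
    all_counts = np.concatenate([counts, ercc_counts], axis=1)

    truth_nuclei = pd.DataFrame(
        {"z": z, "cell_type": cell_type, "ploidy": ploidy, "efficiency": efficiency},
        index=nuclei.index,
    )

    # technical replicates: re-sequenced copies of the first nuclei (fresh
    # counting noise, same underlying state), flagged for removal
    for r in range(cfg.n_technical_replicates):
        src = r  # row index of the replicated nucleus
        lam = rng.gamma(shape=theta[src], scale=mu[src] / theta[src])
        rep_counts = rng.poisson(lam)
        rep_ercc = rng.poisson(ercc_mu[src])
        all_counts = np.vstack([all_counts, np.concatenate([rep_counts, rep_ercc])])
        rep_id = f"{nucleus_ids[src]}-R2"
        nuclei.loc[rep_id] = nuclei.iloc[src]
        nuclei.loc[rep_id, "is_technical_replicate"] = True
        truth_nuclei.loc[rep_id] = truth_nuclei.iloc[src]

    cm = CountMatrix(counts=all_counts, features=feature_table, nuclei=nuclei)
    truth = GroundTruth(
        nuclei=truth_nuclei,
        genes=genes.drop(columns=["gene_name"]),
        planted_enrichment=cfg.planted_enrichment,
        detection_scale_4n=s4,
        detection_fold=cfg.detection_fold_4n,
    )
    return cm, truth


def expected_summaries(cfg: SimulationConfig) -> dict:
    """Closed-form expectations under the configured conditions (test oracles)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    # regenerate the gene means exactly as simulate_dataset draws them
    named = _named_genes()
    base = rng.lognormal(cfg.gene_mean_loc, cfg.gene_mean_scale, cfg.n_genes)

    conc = ercc_concentration_table(cfg.n_ercc)
    ercc_totals = dict(cfg.ercc_total_by_dilution)
    mean_eff = math.exp(cfg.efficiency_sigma**2 / 2.0)

    det_2n = _nb_detection_prob(base, cfg.theta_2n).sum()
    s4_flat = _solve_detection_scale(base, cfg.theta_2n, cfg.theta_4n, cfg.detection_fold_4n)
    det_4n = _nb_detection_prob(s4_flat * base, cfg.theta_4n).sum()
    endo_total_2n = base.sum() * mean_eff
    return {
        "expected_detected_2n": float(det_2n),
        "expected_detected_4n": float(det_4n),
        "expected_detection_fold": float(det_4n / det_2n),
        "expected_ercc_total": {k: v * mean_eff for k, v in ercc_totals.items()},
        "expected_endogenous_total_2n": float(endo_total_2n),
        "expected_cv_fraction": {"2n": 0.5, "4n": cfg.pericentral_fraction_4n},
        "planted_enrichment": cfg.planted_enrichment,
        "nb_variance": lambda mu, theta: mu + mu**2 / theta,
        "named_genes": named,
    }
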