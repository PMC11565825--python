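"""Synthetic data generation for the full pipeline.

Generates the five inputs the analysis consumes — a sample x protein
abundance matrix with clinical metadata, a physical-interaction edge list, a
labeled cell x gene expression matrix, and a histopathology table — with the
statistical structure the downstream stages assume planted and recoverable:

* block co-expression modules (shared latent factor per module);
* an anchor protein pair (stand-ins for APP and MAPT) whose dependence is
  moderated by designated moderator proteins;
* per-subtype marker gene sets in the cell data, plus one subtype whose
  frequency rises across pathology conditions;
* a planted amyloid x moderator interaction effect on tau burden in the
  histopathology table, restricted to configured (region, dementia) strata.

Every generator is a pure function of a :class:`SynthConfig`; fixing the
seed fixes every artifact bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Abundance, CellData, WeightedNetwork, warn

__all__ = ["SynthConfig", "ConfigError", "gen_abundance", "gen_ppi", "gen_cells", "gen_histo", "write_all"]

REGIONS = ("FWM", "HIP", "PCx", "TCx")
CONDITIONS = ("Control", "Abeta", "AbetaTau")


class ConfigError(ValueError):
    """Inconsistent synthetic-data configuration."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate a mid-sized TMT proteomics cohort: 300 retained
    samples, 260 proteins of which 200 sit in five co-expression modules,
    one planted moderator of the anchor-pair dependence, and a physical
    interaction network enriched within modules.
    """

    n_samples: int = 300
    n_proteins: int = 260
    module_sizes: tuple[int, ...] = (20, 30, 40, 50, 60)
    within_module_corr: float = 0.7
    anchor_pair: tuple[str, str] = ("APP", "MAPT")
    moderator_names: tuple[str, ...] = ("HSPA5",)
    moderator_effect: float = 0.8
    noise_sd: float = 0.1
    missing_rate: float = 0.0
    ppi_density: float = 0.05
    ppi_within_module_enrichment: float = 10.0
    n_cells: int = 2000
    n_subtypes: int = 4
    marker_genes_per_subtype: int = 10
    marker_shift: float = 1.0
    n_donors_per_condition: int = 4
    histo_donors_per_status: int = 150
    histo_beta_interaction: float = 5.0
    histo_betas: tuple[float, float, float] = (5.0, 0.5, 0.3)  # beta0, beta_abeta, beta_m
    histo_noise_sd: float = 1.0
    interaction_strata: tuple[tuple[str, str], ...] = (("TCx", "yes"),)
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_proteins:
            raise ConfigError(
                f"module sizes sum to {sum(self.module_sizes)} > n_proteins={self.n_proteins}"
            )
        for name, v in [
            ("within_module_corr", self.within_module_corr),
            ("moderator_effect", self.moderator_effect),
            ("ppi_density", self.ppi_density),
            ("missing_rate", self.missing_rate),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        names = list(self.anchor_pair) + list(self.moderator_names)
        if len(set(names)) != len(names):
            raise ConfigError("anchor and moderator names must be distinct")
        n_special = len(names)
        if sum(self.module_sizes) + n_special > self.n_proteins:
            raise ConfigError(
                "not enough background proteins to host anchors and moderators"
            )

    # ---- deterministic protein naming and planted structure ----

    def protein_names(self) -> list[str]:
        """Protein (gene symbol) names: module members first, then the
        anchors and moderators, then unstructured background proteins."""
        n_mod = sum(self.module_sizes)
        names = [f"P{i + 1:04d}" for i in range(self.n_proteins)]
        special = list(self.anchor_pair) + list(self.moderator_names)
        for j, s in enumerate(special):
            names[n_mod + j] = s
        return names

    def planted_modules(self) -> pd.Series:
        """Ground-truth module label per protein (0 = background)."""
        labels = np.zeros(self.n_proteins, dtype=int)
        start = 0
        for m, size in enumerate(self.module_sizes, start=1):
            labels[start : start + size] = m
            start += size
        return pd.Series(labels, index=self.protein_names(), name="module")

    def anchor_neighborhood(self) -> list[str]:
        """The anchors, moderators, and up to 8 background proteins that
        together form the planted co-expression/interaction neighborhood
        around the amyloid/tau axis."""
        special = list(self.anchor_pair) + list(self.moderator_names)
        background = [
            p for p in self.protein_names()
            if self.planted_modules()[p] == 0 and p not in special
        ]
        return special + background[:8]

    def marker_sets(self) -> dict[str, list[str]]:
        """Planted marker genes per cell subtype (disjoint, deterministic)."""
        rng = np.random.default_rng([self.seed, 4])
        genes = self.protein_names()
        picks = rng.choice(
            len(genes), size=self.n_subtypes * self.marker_genes_per_subtype, replace=False
        )
        out: dict[str, list[str]] = {}
        for s in range(self.n_subtypes):
            sel = picks[s * self.marker_genes_per_subtype : (s + 1) * self.marker_genes_per_subtype]
            out[f"S{s + 1}"] = [genes[i] for i in sorted(sel)]
        return out


def _lam_from_r(r: float) -> float:
    # loading giving corr r when anchor2 = lam*anchor1 + N(0,1)
    r = min(max(r, 0.0), 0.995)
    return r / np.sqrt(1.0 - r * r)


def gen_abundance(config: SynthConfig) -> Abundance:
    """Generate the sample x protein abundance matrix.

    Module members share a latent factor, so pairwise within-module
    correlation is ~ ``within_module_corr`` (diluted by ``noise_sd``).  The
    second anchor's loading on the first is a steep sigmoid of a latent
    moderation variable ``u``; every named moderator protein reads out ``u``
    with high fidelity.  The loading levels are chosen so the anchor-pair
    correlation differs by ``moderator_effect`` between samples with high
    and low moderator abundance.
    """
    rng = np.random.default_rng([config.seed, 0])
    n, p = config.n_samples, config.n_proteins
    names = config.protein_names()
    labels = config.planted_modules().to_numpy()
    rho = config.within_module_corr

    X = np.empty((n, p))
    # module members: shared factor + idiosyncratic noise
    factors = rng.standard_normal((n, config.n_modules))
    for j in range(p):
        m = labels[j]
        if m > 0:
            X[:, j] = np.sqrt(rho) * factors[:, m - 1] + np.sqrt(1 - rho) * rng.standard_normal(n)
        else:
            X[:, j] = rng.standard_normal(n)

    # moderation: a latent u drives the moderators, the anchor coupling,
    # and a small co-expression neighborhood around the anchor axis (so the
    # moderators sit near the anchors in network space, as the screening
    # step presumes)
    u = rng.standard_normal(n)
    name_to_col = {nm: j for j, nm in enumerate(names)}
    special = set(config.anchor_pair) | set(config.moderator_names)
    for nb in config.anchor_neighborhood():
        if nb not in special:
            X[:, name_to_col[nb]] = np.sqrt(0.6) * u + np.sqrt(0.4) * rng.standard_normal(n)
    # planted moderators read the latent out directly; only the global
    # measurement noise (added below) separates them from u
    for mod in config.moderator_names:
        X[:, name_to_col[mod]] = u

    e = config.moderator_effect
    lam_lo = _lam_from_r((1.0 - e) / 2.0)
    lam_hi = _lam_from_r((1.0 + e) / 2.0)
    # steep sigmoid: the coupling switches essentially within the middle
    # tercile of u, so the outer terciles see near-constant loadings
    lam = lam_lo + (lam_hi - lam_lo) / (1.0 + np.exp(-u / 0.1))
    a1, a2 = (name_to_col[a] for a in config.anchor_pair)
    anchor1 = 0.5 * u + np.sqrt(0.75) * rng.standard_normal(n)
    X[:, a1] = anchor1
    # anchor2: moderated coupling to anchor1, plus a small direct loading
    # on the neighborhood latent (within a stratum u is nearly constant,
    # so this leaves the within-stratum coupling essentially untouched)
    X[:, a2] = lam * anchor1 + 0.4 * u + np.sqrt(0.84) * rng.standard_normal(n)

    # measurement noise + positive abundance offset
    X = 10.0 + X + config.noise_sd * rng.standard_normal((n, p))
    if config.missing_rate > 0:
        mask = rng.random((n, p)) < config.missing_rate
        X[mask] = np.nan

    samples = [f"S{i + 1:04d}" for i in range(n)]
    diagnosis = rng.choice(
        ["NCI", "MCI", "AD-dementia", "other"], size=n, p=[0.2, 0.35, 0.35, 0.1]
    )
    mmse = np.empty(n, dtype=int)
    for i, d in enumerate(diagnosis):
        lo, hi = {"NCI": (27, 30), "MCI": (21, 29), "AD-dementia": (5, 28), "other": (10, 30)}[d]
        mmse[i] = rng.integers(lo, hi + 1)
    meta = pd.DataFrame({"diagnosis": diagnosis, "mmse": mmse}, index=samples)
    values = pd.DataFrame(X, index=samples, columns=names)
    return Abundance(values=values, meta=meta)


def gen_ppi(config: SynthConfig, proteins: list[str] | None = None) -> WeightedNetwork:
    """Generate a STRING-style physical interaction network.

    Edge probability is ``ppi_density`` between modules and
    ``min(1, ppi_density * ppi_within_module_enrichment)`` within a module.
    The anchors, the moderators, and a few background proteins form an
    "anchor neighborhood" with within-module edge probability, emulating
    the physical interactome around the amyloid/tau axis so that planted
    moderators are embedded near the anchors.  Scores are uniform on
    [0.5, 1].
    """
    if proteins is None:
        proteins = config.protein_names()
    if not proteins:
        raise ConfigError("protein list is empty")
    rng = np.random.default_rng([config.seed, 1])
    modules = config.planted_modules()
    labels = np.array([modules.get(p, 0) for p in proteins])
    n = len(proteins)

    if config.ppi_density == 0 and np.isinf(config.ppi_within_module_enrichment):
        p_within = 1.0
    else:
        p_within = min(1.0, config.ppi_density * config.ppi_within_module_enrichment)
    p_between = config.ppi_density

    hood = set(config.anchor_neighborhood())
    in_hood = np.array([p in hood for p in proteins])

    iu, ju = np.triu_indices(n, k=1)
    same = ((labels[iu] == labels[ju]) & (labels[iu] > 0)) | (in_hood[iu] & in_hood[ju])
    prob = np.where(same, p_within, p_between)
    keep = rng.random(len(iu)) < prob
    scores = rng.uniform(0.5, 1.0, size=int(keep.sum()))
    prot = np.asarray(proteins)
    edges = pd.DataFrame(
        {"node_a": prot[iu[keep]], "node_b": prot[ju[keep]], "weight": scores}
    )
    return WeightedNetwork(nodes=list(proteins), edges=edges)


def gen_cells(config: SynthConfig) -> CellData:
    """Generate labeled single-cell expression counts.

    Each subtype overexpresses its planted marker set by a factor of
    ``exp(marker_shift)``; subtype S1 has a planted frequency gradient
    Control < Abeta < AbetaTau.  Counts are Poisson around lognormal
    per-gene baselines; cells are distributed over donors per condition so
    that per-donor composition tests are possible.
    """
    if config.n_subtypes < 2:
        raise ConfigError("n_subtypes must be >= 2")
    rng = np.random.default_rng([config.seed, 2])
    genes = config.protein_names()
    markers = config.marker_sets()
    subtypes = list(markers)
    g_index = {g: i for i, g in enumerate(genes)}

    # subtype frequencies per condition: S1 rises with pathology
    freqs = {}
    for c, p1 in zip(CONDITIONS, (0.10, 0.20, 0.30)):
        rest = (1.0 - p1) / (config.n_subtypes - 1)
        freqs[c] = np.array([p1] + [rest] * (config.n_subtypes - 1))

    n_per_cond = config.n_cells // len(CONDITIONS)
    base = np.exp(rng.normal(0.0, 0.5, size=len(genes)))

    rows, subtype_lab, cond_lab, donor_lab = [], [], [], []
    for c in CONDITIONS:
        donors = [f"{c}_D{d + 1}" for d in range(config.n_donors_per_condition)]
        sub = rng.choice(subtypes, size=n_per_cond, p=freqs[c])
        don = np.repeat(donors, int(np.ceil(n_per_cond / len(donors))))[:n_per_cond]
        for s, d in zip(sub, don):
            lam = base.copy()
            idx = [g_index[g] for g in markers[s]]
            lam[idx] *= np.exp(config.marker_shift)
            rows.append(rng.poisson(lam))
            subtype_lab.append(s)
            cond_lab.append(c)
            donor_lab.append(d)

    cells = [f"C{i + 1:05d}" for i in range(len(rows))]
    values = pd.DataFrame(np.array(rows, dtype=float), index=cells, columns=genes)
    labels = pd.DataFrame(
        {"subtype": subtype_lab, "condition": cond_lab, "donor": donor_lab}, index=cells
    )
    return CellData(values=values, labels=labels)


def gen_histo(config: SynthConfig) -> pd.DataFrame:
    """Generate the histopathology table: donor x region rows with %area
    immunoreactivity measures, a bulk expression column, and semi-quantitative
    severity scores.

    Tau2 %area is ``b0 + b1*Abeta + b2*GFAP + b3*(Abeta*GFAP) + eps`` where
    ``b3 = histo_beta_interaction`` only in ``interaction_strata`` and 0
    elsewhere.  Braak stage tracks donor-level tau burden, CERAD tracks
    amyloid burden (1 = definite AD), and GPNMB FPKM rises with Braak.
    """
    rng = np.random.default_rng([config.seed, 3])
    b0, b1, b2 = config.histo_betas
    n_d = config.histo_donors_per_status
    donors, statuses = [], []
    for status in ("no", "yes"):
        for i in range(n_d):
            donors.append(f"{status}_{i + 1:04d}")
            statuses.append(status)

    recs = []
    for donor, status in zip(donors, statuses):
        for region in REGIONS:
            abeta = abs(rng.normal(3.0 if status == "yes" else 1.5, 1.0))
            gfap = abs(rng.normal(2.0, 1.0))
            iba1 = abs(rng.normal(1.5, 1.0))
            b3 = config.histo_beta_interaction if (region, status) in config.interaction_strata else 0.0
            eps = rng.normal(0.0, config.histo_noise_sd) if config.histo_noise_sd > 0 else 0.0
            tau2 = b0 + b1 * abeta + b2 * gfap + b3 * abeta * gfap + eps
            at8 = max(0.0, 0.8 * tau2 + rng.normal(0.0, 0.5))
            recs.append(
                {
                    "donor": donor,
                    "region": region,
                    "dementia": status,
                    "abeta_pct": abeta,
                    "tau2_pct": max(0.0, tau2),
                    "at8_pct": at8,
                    "gfap_pct": gfap,
                    "iba1_pct": iba1,
                }
            )
    df = pd.DataFrame(recs)

    # donor-level severity scores from mean burden ranks
    mean_tau = df.groupby("donor")["tau2_pct"].mean()
    mean_abeta = df.groupby("donor")["abeta_pct"].mean()
    braak = pd.Series(
        np.minimum((mean_tau.rank(method="first") - 1) // (len(mean_tau) / 7), 6).astype(int),
        index=mean_tau.index,
        name="braak",
    )
    cerad = pd.Series(
        4 - np.minimum((mean_abeta.rank(method="first") - 1) // (len(mean_abeta) / 4), 3).astype(int),
        index=mean_abeta.index,
        name="cerad",
    )
    gpnmb = pd.Series(
        np.exp(rng.normal(0.0, 0.3, size=len(braak))) * (1.0 + 0.5 * braak.to_numpy()),
        index=braak.index,
        name="gpnmb_fpkm",
    )
    df = df.merge(braak, on="donor").merge(cerad, on="donor").merge(gpnmb, on="donor")
    return df


def write_all(config: SynthConfig, outdir) -> dict[str, Path]:
    """Generate every artifact and write it as TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": outdir / "abundance.tsv",
        "ppi": outdir / "ppi.tsv",
        "cells": outdir / "cells.tsv",
        "cell_labels": outdir / "cell_labels.tsv",
        "histo": outdir / "histo.tsv",
        "truth_modules": outdir / "truth_modules.tsv",
    }
    gen_abundance(config).to_tsv(paths["abundance"])
    gen_ppi(config).to_tsv(paths["ppi"])
    gen_cells(config).to_tsv(paths["cells"], paths["cell_labels"])
    gen_histo(config).to_csv(paths["histo"], sep="\t", index=False)
    config.planted_modules().rename_axis("protein").to_csv(paths["truth_modules"], sep="\t")
    return paths
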