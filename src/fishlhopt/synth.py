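"""Synthetic data with known ground truth for every pipeline input.

Every table the calibration stage consumes can be generated here with a
recorded generative truth, so the full chain — gradient fits, growth-curve
and allocation-rate fits, fecundity mixed model, SST profile — can be
exercised end to end and checked for parameter recovery without any
external data.

The default :class:`SynthTruth` equals the published calibration (gradient
coefficients, egg-count fixed effects, h = 0.26), with noise levels chosen
to resemble the compiled literature data: lognormal scatter of sd 0.5 on
mortality (the published gradient explains only a small share of variance),
0.35/0.4 on the growth and offspring-size parameters, 10% multiplicative
noise on mass-at-age, and species effects of sd 0.3 (intercept) and 0.05
(mass slope) around the fecundity fixed effects with residual sd 0.5.

A single integer seed controls each generator through
``numpy.random.default_rng``; generated frames embed the seed in
``DataFrame.attrs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .growth import AllocationSchedule, GrowthParams, weight_at

__all__ = [
    "SynthTruth",
    "default_truth",
    "simulate_mortality_records",
    "simulate_mass_at_age",
    "simulate_fecundity_observations",
    "simulate_a50_records",
    "synthetic_sst",
]


@dataclass(frozen=True)
class SynthTruth:
    """Generative parameters for all synthetic tables."""

    # ln-scale latitude gradients: value = exp(a + b * |lat|)
    m_a: float = -0.31
    m_b: float = -0.02
    k_a: float = 1.47
    k_b: float = -0.01
    w0_a: float = 2.67
    w0_b: float = 0.00
    sigma_m: float = 0.5
    sigma_k: float = 0.35
    sigma_w0: float = 0.4
    # egg-count model fixed effects and variance components
    fec_c: float = 5.39
    fec_d: float = -0.02
    rs_a: float = 1.00
    rs_b: float = 0.004
    sd_species_intercept: float = 0.3
    sd_species_slope: float = 0.05
    sigma_f: float = 0.5
    # growth trajectories
    h: float = 0.26
    sigma_growth: float = 0.1
    # A50 gradient (ln scale)
    a50_a: float = -0.28
    a50_b: float = field(default=float(np.log(5.87 / 0.76) / 60.0))
    sigma_a50: float = 0.3


def default_truth() -> SynthTruth:
    """The published-calibration truth used throughout the test-suite."""
    return SynthTruth()


def _stamp(df: pd.DataFrame, seed) -> pd.DataFrame:
    df.attrs["seed"] = seed
    return df


def simulate_mortality_records(
    truth: SynthTruth,
    n_species: int = 82,
    seed: int = 0,
    sigma: float | None = None,
    replicate_refs: int = 0,
) -> pd.DataFrame:
    """Natural-mortality records along the latitudinal gradient.

    One species per row by default; ``replicate_refs > 0`` adds that many
    extra same-reference rows (jittered M and latitude) for a random subset
    of species, to exercise per-reference aggregation.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(seed)
    sigma = truth.sigma_m if sigma is None else sigma
    lat = rng.uniform(0.0, 75.0, n_species)
    lnM = truth.m_a + truth.m_b * lat + rng.normal(0.0, sigma, n_species)
    df = pd.DataFrame(
        {
            "species": [f"species_{i:03d}" for i in range(n_species)],
            "reference": [f"ref_{i // 2:03d}" for i in range(n_species)],
            "latitude": lat,
            "M": np.exp(lnM),
        }
    )
    if replicate_refs > 0:
        picks = rng.choice(n_species, size=min(replicate_refs, n_species), replace=False)
        extra = df.iloc[picks].copy()
        extra["latitude"] = np.clip(extra["latitude"] + rng.normal(0, 2.0, len(extra)), 0, 75)
        extra["M"] = extra["M"] * np.exp(rng.normal(0, 0.1, len(extra)))
        df = pd.concat([df, extra], ignore_index=True)
    df["LnM"] = np.log(df["M"])
    return _stamp(df, seed)


def simulate_mass_at_age(
    truth: SynthTruth,
    gp: GrowthParams,
    ages,
    seed: int = 0,
    alpha: float | None = None,
    sigma: float | None = None,
) -> pd.DataFrame:
    """Mass-at-age observations from the closed-form trajectory.

    With ``alpha=None`` the trajectory is pre-maturity only (for growth-curve
    fitting: all ages must then precede maturity by construction of the
    caller's age grid).  Supplying ``alpha`` generates the full two-branch
    trajectory with the truth's allocation rate ``h`` (for estimating h).
    Noise is multiplicative lognormal with sd ``sigma_growth``.
    """
    ages = np.asarray(ages, dtype=float)
    if len(ages) == 0:
        raise ValueError("ages must be non-empty")
    rng = np.random.default_rng(seed)
    sigma = truth.sigma_growth if sigma is None else sigma
    if alpha is None:
        sched = AllocationSchedule(alpha=float(ages.max()) + 1.0, h=truth.h)
        pre = np.ones(len(ages), dtype=bool)
    else:
        sched = AllocationSchedule(alpha=alpha, h=truth.h)
        pre = ages < alpha
    mass = weight_at(ages, gp, sched) * np.exp(rng.normal(0.0, sigma, len(ages)))
    df = pd.DataFrame({"age": ages, "mass_g": mass, "pre_maturity": pre})
    return _stamp(df, seed)


def _brownian_effects(tree: dendropy.Tree, sd: float, rng: np.random.Generator) -> dict:
    """Species intercept deviations from Brownian motion along the tree."""
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    n = len(taxa)
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    cov = np.empty((n, n))
    for i, a in enumerate(taxa):
        cov[i, i] = tree.mrca(taxa=[tax[a]]).distance_from_root()
        for j in range(i + 1, n):
            cov[i, j] = cov[j, i] = pdm.mrca(tax[a], tax[taxa[j]]).distance_from_root()
    cov = cov / np.mean(np.diag(cov)) * sd**2
    draws = rng.multivariate_normal(np.zeros(n), cov, method="svd")
    return dict(zip(taxa, draws))


def simulate_fecundity_observations(
    truth: SynthTruth,
    n_species: int = 40,
    n_per_species: int = 30,
    tree: bool = False,
    seed: int = 0,
    decoy_excluded: bool = False,
):
    """Batch-fecundity observations under the egg-count model.

    Species latitudes are uniform on [0, 75]; per-species masses are
    lognormal around a species-specific centre; egg counts follow
    ``ln F = c + d*lat + (RS_a + RS_b*lat + species_slope) * ln m +
    species_intercept + noise``.  With ``tree=True`` a birth-death phylogeny
    is simulated and the species intercepts gain a Brownian component on it
    (returned as the second element, else ``None``).  ``decoy_excluded``
    appends an elasmobranch-flagged species that curation must remove.
    """
    if n_per_species < 10:
        raise ValueError("fewer than 10 records per species would not survive curation")
    rng = np.random.default_rng(seed)
    names = [f"fish_{i:03d}" for i in range(n_species)]

    phylo = None
    bm = {sp: 0.0 for sp in names}
    if tree:
        taxa = dendropy.TaxonNamespace(names)
        import random as _random

        phylo = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.2,
            num_extant_tips=n_species,
            taxon_namespace=taxa,
            rng=_random.Random(int(seed) % 2**31),
        )
        for leaf, name in zip(phylo.leaf_node_iter(), names):
            leaf.taxon.label = name
        bm = _brownian_effects(phylo, truth.sd_species_intercept, rng)

    rows = []
    for sp in names:
        lat = rng.uniform(0.0, 75.0)
        u_int = bm[sp] if tree else rng.normal(0.0, truth.sd_species_intercept)
        u_slope = rng.normal(0.0, truth.sd_species_slope)
        ln_centre = rng.uniform(np.log(50.0), np.log(5000.0))
        ln_mass = rng.normal(ln_centre, 0.8, n_per_species)
        rs = truth.rs_a + truth.rs_b * lat + u_slope
        ln_f = (
            truth.fec_c
            + truth.fec_d * lat
            + rs * ln_mass
            + u_int
            + rng.normal(0.0, truth.sigma_f, n_per_species)
        )
        for lm, lf in zip(ln_mass, ln_f):
            rows.append(
                {
                    "species": sp,
                    "mass_g": float(np.exp(lm)),
                    "fecundity": float(np.exp(lf)),
                    "abs_lat": lat,
                    "year": 2000,
                    "location": "site_A",
                    "is_freshwater_migrant": False,
                    "is_elasmobranch": False,
                    "is_tuna": False,
                }
            )
    df = pd.DataFrame(rows)
    if decoy_excluded:
        decoy = df.iloc[:n_per_species].copy()
        decoy["species"] = "decoy_ray"
        decoy["is_elasmobranch"] = True
        df = pd.concat([df, decoy], ignore_index=True)
    return _stamp(df, seed), phylo


def simulate_a50_records(
    truth: SynthTruth,
    n: int = 60,
    seed: int = 0,
    frac_indirect: float = 0.0,
) -> pd.DataFrame:
    """Age-at-50%-maturity records along the latitudinal gradient."""
    rng = np.random.default_rng(seed)
    lat = rng.uniform(0.0, 75.0, n)
    a50 = np.exp(truth.a50_a + truth.a50_b * lat + rng.normal(0.0, truth.sigma_a50, n))
    direct = rng.random(n) >= frac_indirect
    df = pd.DataFrame({"abs_lat": lat, "a50": a50, "direct": direct})
    return _stamp(df, seed)


def synthetic_sst(
    kind: str = "sigmoid",
    seed: int | None = None,
    noise_sd: float = 0.0,
    lat_step: float = 0.5,
) -> pd.DataFrame:
    """Present-day mean SST by absolute latitude.

    ``kind="linear"`` is the analytic profile ``28 - 0.3 * lat``;
    ``kind="sigmoid"`` mimics the observed climatology: a warm plateau of
    27-28 C below ~20 deg falling smoothly toward ~1 C at 75 deg.
    """
    lat = np.arange(0.0, 75.0 + 1e-9, lat_step)
    if kind == "linear":
        sst = 28.0 - 0.3 * lat
    elif kind == "sigmoid":
        sst = 0.5 + 27.5 / (1.0 + np.exp((lat - 45.0) / 7.0))
    else:
        raise ValueError(f"unknown SST profile kind {kind!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sst = sst + rng.normal(0.0, noise_sd, len(lat))
    df = pd.DataFrame({"lat": lat, "sst": sst})
    return _stamp(df, seed)
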