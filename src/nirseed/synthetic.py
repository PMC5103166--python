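"""Synthetic study generator: mixture NIR spectra with scatter artifacts,
correlated seed-composition references, and RIL populations with planted
additive QTL.

What is emulated
----------------
* Reference concentrations follow the observed calibration-set statistics of
  the four seed components (defaults: oil 38.78 +/- 3.88 % over 18.70-46.90,
  protein 19.99 +/- 3.39 over 11.89-27.73, carbon 57.39 +/- 1.25 over
  51.41-60.69, nitrogen tied to protein through the conventional 6.25
  protein-to-nitrogen conversion factor), with the oil-protein negative
  correlation built in.
* Spectra are linear mixtures of band-shaped component signatures on a
  shared baseline, distorted per sample by a multiplicative scatter slope
  and an additive offset (what MSC removes) plus white channel noise.
* RIL genotypes follow a Markov chain along each chromosome whose
  adjacent-marker switch probability is the selfed-RIL map expansion
  R = 2r/(1+2r) of the Haldane recombination fraction
  r = (1 - exp(-2d/100))/2; chromosomes segregate independently.

Every generator is fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    COMPONENTS,
    GeneticMap,
    PhenotypeTable,
    ReferenceTable,
    RILPopulation,
    SpectraSet,
    WavenumberGrid,
)

__all__ = [
    "ComponentSignature",
    "SimulationTruth",
    "DEFAULT_TARGETS",
    "DEFAULT_SIGNATURES",
    "NITROGEN_CONVERSION",
    "default_grid",
    "default_signatures",
    "default_map",
    "baseline_spectrum",
    "simulate_concentrations",
    "simulate_spectra",
    "simulate_ril_population",
    "simulate_ril_phenotypes",
    "simulate_culture_trial",
    "haldane_r",
    "ril_expansion",
]

#: Conventional nitrogen-to-protein conversion factor.
NITROGEN_CONVERSION = 6.25

#: Per-component concentration targets (mean, SD, range in % dry weight),
#: matching the calibration-set statistics the package is designed around.
DEFAULT_TARGETS = {
    "oil": {"mean": 38.78, "sd": 3.88, "range": (18.70, 46.90)},
    "protein": {"mean": 19.99, "sd": 3.39, "range": (11.89, 27.73)},
    "carbon": {"mean": 57.39, "sd": 1.25, "range": (51.41, 60.69)},
    "nitrogen": {"mean": 4.34, "sd": 0.43, "range": (3.14, 5.52)},
}

DEFAULT_OIL_PROTEIN_CORR = -0.7
#: SD (%) of the noise on nitrogen around protein / 6.25.
NITROGEN_NOISE_SD = 0.05

#: Scatter and channel-noise defaults for an FT-NIR-like instrument:
#: path-length-type multiplicative slope SD 0.10, baseline offset SD 0.05 AU,
#: white channel noise 5e-4 AU.
DEFAULT_SCATTER_SLOPE_SD = 0.10
DEFAULT_SCATTER_OFFSET_SD = 0.05
DEFAULT_NOISE_SD = 5e-4


@dataclass(frozen=True)
class ComponentSignature:
    """Pure-component spectrum as a sum of Gaussian bands.

    Amplitudes are absorbance units per % concentration; centers/widths in
    cm^-1.  Bands of different components overlap by design, so calibration
    genuinely requires a multivariate model.
    """

    component: str
    centers: tuple
    widths: tuple
    amplitudes: tuple

    def __post_init__(self):
        if not (len(self.centers) == len(self.widths) == len(self.amplitudes)):
            raise ValueError("centers, widths, amplitudes must align")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("band amplitudes must be >= 0")

    def evaluate(self, grid: WavenumberGrid) -> np.ndarray:
        v = grid.values
        out = np.zeros_like(v)
        for c, w, a in zip(self.centers, self.widths, self.amplitudes):
            out += a * np.exp(-0.5 * ((v - c) / w) ** 2)
        return out


# Band positions loosely follow NIR overtone/combination regions: C-H
# (lipid) bands near 4260/5800/8250, N-H (protein) near 4600/6000/6670,
# broad C-H/C-C combination structure for carbon, amide-associated bands for
# nitrogen.  Values are invented stand-ins for true seed component spectra.
DEFAULT_SIGNATURES = (
    ComponentSignature(
        "oil", (4260.0, 4340.0, 5680.0, 5800.0, 8250.0),
        (30.0, 40.0, 60.0, 50.0, 90.0),
        (0.012, 0.009, 0.008, 0.010, 0.004),
    ),
    ComponentSignature(
        "protein", (4600.0, 4870.0, 6000.0, 6670.0),
        (45.0, 55.0, 70.0, 80.0),
        (0.010, 0.008, 0.006, 0.005),
    ),
    ComponentSignature(
        "carbon", (4400.0, 5200.0, 5900.0, 7000.0, 8400.0),
        (120.0, 150.0, 100.0, 110.0, 140.0),
        (0.004, 0.003, 0.0035, 0.002, 0.0015),
    ),
    ComponentSignature(
        "nitrogen", (4680.0, 5180.0, 6520.0),
        (40.0, 60.0, 70.0),
        (0.015, 0.010, 0.008),
    ),
)


def default_grid(resolution: float = 8.0) -> WavenumberGrid:
    """Instrument grid: 4000-10000 cm^-1 at 8 cm^-1 optical resolution."""
    return WavenumberGrid(np.arange(4000.0, 10000.0 + resolution / 2, resolution),
                          resolution)


def default_signatures():
    return DEFAULT_SIGNATURES


def baseline_spectrum(grid: WavenumberGrid) -> np.ndarray:
    """Shared smooth seed-matrix baseline (broad slope + water-like hump)."""
    v = grid.values
    return (
        0.35
        + 4e-5 * (v - 4000.0)
        + 0.15 * np.exp(-0.5 * ((v - 5200.0) / 700.0) ** 2)
    )


@dataclass
class SimulationTruth:
    """Everything needed to verify a simulated study against ground truth."""

    seed: int
    concentrations: pd.DataFrame | None = None  # sample x component, true %
    signatures: tuple = ()
    scatter_slope: np.ndarray | None = None
    scatter_offset: np.ndarray | None = None
    noise_sd: float | None = None
    qtl: list | None = None          # dicts: chr, pos_cM, effect, genotype x
    qtl_variance_fractions: list | None = None
    residual_sd: float | None = None
    grand_mean: float | None = None


def _feasible(mean, sd, lo, hi):
    if sd <= 0:
        return False
    if not (lo < mean < hi):
        return False
    # a normal truncated to [lo, hi] cannot hold its SD if the window is
    # narrower than ~2 SD around the mean
    return (hi - lo) >= 2.0 * sd


def simulate_concentrations(
    n: int,
    targets: dict | None = None,
    oil_protein_corr: float = DEFAULT_OIL_PROTEIN_CORR,
    seed: int = 0,
    nitrogen_conversion: float = NITROGEN_CONVERSION,
) -> tuple[ReferenceTable, SimulationTruth]:
    """Draw correlated reference concentrations for n samples.

    Oil and protein come from a bivariate normal with the requested
    (non-positive) correlation; carbon is drawn independently; nitrogen is
    protein / ``nitrogen_conversion`` plus N(0, 0.05) noise, mirroring the
    biochemical protein--nitrogen coupling.  With the conventional factor
    6.25 the nitrogen level tracks protein/6.25 rather than any separate
    nitrogen target, since nitrogen is a derived quantity here.  Draws
    outside a component's range are rejected and redrawn, so empirical
    moments track the targets.
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    if not (-1.0 <= oil_protein_corr <= 0.0):
        raise ValueError("oil_protein_corr must lie in [-1, 0]")
    t = dict(DEFAULT_TARGETS)
    if targets:
        for k, v in targets.items():
            t[k] = {**DEFAULT_TARGETS[k], **v}
    for comp in ("oil", "protein", "carbon"):
        m, s = t[comp]["mean"], t[comp]["sd"]
        lo, hi = t[comp]["range"]
        if not _feasible(m, s, lo, hi):
            raise ValueError(f"infeasible mean/SD/range for {comp}")
    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [t["oil"]["sd"] ** 2, oil_protein_corr * t["oil"]["sd"] * t["protein"]["sd"]],
            [oil_protein_corr * t["oil"]["sd"] * t["protein"]["sd"], t["protein"]["sd"] ** 2],
        ]
    )
    mean_op = np.array([t["oil"]["mean"], t["protein"]["mean"]])
    op = np.empty((0, 2))
    while op.shape[0] < n:  # rejection sampling into the stated ranges
        draw = rng.multivariate_normal(mean_op, cov, size=2 * n)
        ok = (
            (draw[:, 0] >= t["oil"]["range"][0])
            & (draw[:, 0] <= t["oil"]["range"][1])
            & (draw[:, 1] >= t["protein"]["range"][0])
            & (draw[:, 1] <= t["protein"]["range"][1])
        )
        op = np.vstack([op, draw[ok]])
    op = op[:n]
    carbon = np.empty(0)
    while carbon.size < n:
        draw = rng.normal(t["carbon"]["mean"], t["carbon"]["sd"], size=2 * n)
        lo, hi = t["carbon"]["range"]
        carbon = np.concatenate([carbon, draw[(draw >= lo) & (draw <= hi)]])
    carbon = carbon[:n]
    nitrogen = op[:, 1] / nitrogen_conversion + rng.normal(0, NITROGEN_NOISE_SD, n)
    nitrogen = np.clip(nitrogen, 1e-3, None)
    ids = [f"S{i + 1:04d}" for i in range(n)]
    conc = pd.DataFrame(
        {
            "oil": op[:, 0],
            "protein": op[:, 1],
            "carbon": carbon,
            "nitrogen": nitrogen,
        },
        index=ids,
    )
    records = conc.reset_index(names="sample_id").melt(
        id_vars="sample_id", var_name="component", value_name="value"
    )
    records["method"] = "simulated"
    order = {c: i for i, c in enumerate(COMPONENTS)}
    records = records.sort_values(
        ["sample_id", "component"], key=lambda s: s.map(order) if s.name == "component" else s
    ).reset_index(drop=True)
    truth = SimulationTruth(seed=seed, concentrations=conc)
    return ReferenceTable(records), truth


def simulate_spectra(
    refs: ReferenceTable,
    signatures=DEFAULT_SIGNATURES,
    grid: WavenumberGrid | None = None,
    scatter_slope_sd: float = DEFAULT_SCATTER_SLOPE_SD,
    scatter_offset_sd: float = DEFAULT_SCATTER_OFFSET_SD,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> tuple[SpectraSet, SimulationTruth]:
    """Mixture spectra with per-sample scatter distortion.

    spectrum_i = m_i * (sum_c conc_ic * signature_c + baseline) + a_i + noise
    with m_i ~ N(1, slope_sd) truncated positive and a_i ~ N(0, offset_sd).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if grid is None:
        grid = default_grid()
    sig_map = {s.component: s for s in signatures}
    comps = sorted(set(refs.records["component"]))
    missing = [c for c in comps if c not in sig_map]
    if missing:
        raise ValueError(f"no signature for components: {missing}")
    wide = refs.records.pivot(index="sample_id", columns="component", values="value")
    wide = wide.loc[sorted(wide.index)]
    ids = [str(i) for i in wide.index]
    n = len(ids)
    rng = np.random.default_rng(seed)
    S = np.vstack([sig_map[c].evaluate(grid) for c in comps])  # comps x p
    C = wide[comps].to_numpy(float)                            # n x comps
    clean = C @ S + baseline_spectrum(grid)
    if scatter_slope_sd > 0:
        m = rng.normal(1.0, scatter_slope_sd, n)
        while np.any(m <= 0):
            bad = m <= 0
            m[bad] = rng.normal(1.0, scatter_slope_sd, int(bad.sum()))
    else:
        m = np.ones(n)
    a = rng.normal(0.0, scatter_offset_sd, n) if scatter_offset_sd > 0 else np.zeros(n)
    noise = rng.normal(0.0, noise_sd, clean.shape) if noise_sd > 0 else 0.0
    absorbance = m[:, None] * clean + a[:, None] + noise
    truth = SimulationTruth(
        seed=seed,
        concentrations=wide[comps],
        signatures=tuple(sig_map[c] for c in comps),
        scatter_slope=m,
        scatter_offset=a,
        noise_sd=noise_sd,
    )
    return SpectraSet(grid, absorbance, ids), truth


# ---------------------------------------------------------------------------
# RIL genetics

def haldane_r(d_cM) -> np.ndarray:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, float) / 100.0))


def ril_expansion(r) -> np.ndarray:
    """Observed recombinant fraction between selfed-RIL genotypes: 2r/(1+2r)."""
    r = np.asarray(r, float)
    return 2.0 * r / (1.0 + 2.0 * r)


def default_map(
    n_chromosomes: int = 5, length_cM: float = 87.0, spacing_cM: float = 3.0
) -> GeneticMap:
    """Stand-in linkage map: 5 chromosomes of ~87 cM, evenly spaced markers.

    The true marker density of the emulated population is not published;
    this regular map is a synthetic stand-in.
    """
    chroms = [str(i + 1) for i in range(n_chromosomes)]
    markers, positions = {}, {}
    for c in chroms:
        pos = np.arange(0.0, length_cM + spacing_cM / 2, spacing_cM)
        markers[c] = [f"m{c}_{int(round(p))}" for p in pos]
        positions[c] = pos
    return GeneticMap(chroms, markers, positions)


def simulate_ril_population(
    gmap: GeneticMap, n_lines: int, seed: int = 0
) -> RILPopulation:
    """Simulate homozygous RIL genotypes as a Markov chain along chromosomes.

    The first marker of each chromosome is A or B with probability 1/2; the
    genotype switches between adjacent markers with probability
    R = 2r/(1+2r), r from the Haldane function on the cM interval.
    """
    if n_lines < 2:
        raise ValueError("need n_lines >= 2")
    rng = np.random.default_rng(seed)
    cols = {}
    for chrom in gmap.chromosomes:
        pos = gmap.positions[chrom]
        names = gmap.markers[chrom]
        g = np.zeros((n_lines, len(pos)))
        g[:, 0] = rng.integers(0, 2, n_lines)
        if len(pos) > 1:
            R = ril_expansion(haldane_r(np.diff(pos)))
            switch = rng.random((n_lines, len(pos) - 1)) < R
            for j in range(1, len(pos)):
                g[:, j] = np.where(switch[:, j - 1], 1 - g[:, j - 1], g[:, j - 1])
        for j, name in enumerate(names):
            cols[name] = g[:, j]
    lines = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    return RILPopulation(gmap, pd.DataFrame(cols, index=lines))


def _genotype_at(pop: RILPopulation, chrom: str, pos_cM: float, rng) -> np.ndarray:
    """Draw each line's genotype at an arbitrary position on a chromosome.

    At a marker position the observed genotype is used; between markers the
    genotype is drawn from the two-locus RIL transition probabilities
    conditional on the flanking marker genotypes.
    """
    gmap = pop.map
    mpos = gmap.positions[chrom]
    names = gmap.markers[chrom]
    G = pop.genotypes[names].to_numpy(float)
    j = int(np.argmin(np.abs(mpos - pos_cM)))
    if abs(mpos[j] - pos_cM) < 1e-9 and not np.isnan(G[:, j]).any():
        return G[:, j].copy()
    from .qtl import _prob_b_at  # shared transition algebra

    p_b = _prob_b_at(G, mpos, pos_cM)
    return (rng.random(G.shape[0]) < p_b).astype(float)


def simulate_ril_phenotypes(
    pop: RILPopulation,
    qtl_spec,
    residual_sd: float,
    seed: int = 0,
    trait: str = "trait",
    grand_mean: float = 0.0,
) -> tuple[PhenotypeTable, SimulationTruth]:
    """Additive-QTL phenotypes for a RIL population.

    ``qtl_spec`` is a list of (chromosome, position cM, additive effect)
    triples; coding x = +1 for the B (Ct-1-like) and -1 for the A
    (Col-0-like) allele, so each effect is the mean change from replacing A
    by B.  phenotype = grand_mean + sum effect*x + N(0, residual_sd).  The
    truth records each QTL's realized fraction of phenotypic variance.
    """
    rng = np.random.default_rng(seed)
    n = pop.n_lines
    y = np.full(n, float(grand_mean))
    qtl_truth = []
    contribs = []
    for chrom, pos, effect in qtl_spec:
        chrom = str(chrom)
        if chrom not in pop.map.chromosomes:
            raise ValueError(f"unknown chromosome {chrom}")
        lo, hi = pop.map.positions[chrom][0], pop.map.positions[chrom][-1]
        if not (lo <= pos <= hi):
            raise ValueError(f"QTL position {pos} outside map range [{lo}, {hi}]")
        g = _genotype_at(pop, chrom, float(pos), rng)
        x = 2.0 * g - 1.0
        contribs.append(effect * x)
        y = y + effect * x
        qtl_truth.append(
            {"chr": chrom, "pos_cM": float(pos), "effect": float(effect), "x": x}
        )
    noise = rng.normal(0.0, residual_sd, n) if residual_sd > 0 else np.zeros(n)
    y = y + noise
    total_var = float(np.var(y))
    fractions = [
        float(np.var(c) / total_var) if total_var > 0 else 0.0 for c in contribs
    ]
    records = pd.DataFrame(
        {"line_id": pop.line_ids, "trait": trait, "value": y}
    )
    truth = SimulationTruth(
        seed=seed,
        qtl=qtl_truth,
        qtl_variance_fractions=fractions,
        residual_sd=residual_sd,
        grand_mean=grand_mean,
    )
    return PhenotypeTable(records), truth


def simulate_culture_trial(
    n_genotypes: int = 20,
    n_cultures: int = 3,
    n_replicates: int = 3,
    genotype_sd: float = 1.0,
    culture_sd: float = 0.5,
    interaction_sd: float = 0.3,
    residual_sd: float = 0.5,
    grand_mean: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate-level genotype x culture trial for variance decomposition.

    value = grand_mean + g_i + c_j + (gc)_ij + e_ijk with independent
    Gaussian effects of the stated SDs.  Returns a long DataFrame with
    columns genotype, culture, replicate, value.
    """
    rng = np.random.default_rng(seed)
    g = rng.normal(0.0, genotype_sd, n_genotypes)
    c = rng.normal(0.0, culture_sd, n_cultures)
    gc = rng.normal(0.0, interaction_sd, (n_genotypes, n_cultures))
    rows = []
    for i in range(n_genotypes):
        for j in range(n_cultures):
            e = rng.normal(0.0, residual_sd, n_replicates)
            for k in range(n_replicates):
                rows.append(
                    {
                        "genotype": f"G{i + 1:03d}",
                        "culture": f"C{j + 1}",
                        "replicate": k + 1,
                        "value": grand_mean + g[i] + c[j] + gc[i, j] + e[k],
                    }
                )
    return pd.DataFrame(rows)
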