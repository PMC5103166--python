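"""QTL mapping for RIL populations: Haley--Knott interval mapping,
genome-wide permutation thresholds, cofactor-controlled multiple-QTL scans,
and per-QTL effect / variance-explained estimation.

The workflow mirrors the classical two-pass procedure: a single-QTL genome
scan (IM) finds putative QTL; the closest marker to each peak then serves as
a cofactor controlling the genetic background while re-scanning (MQM);
effects and R-squared come from the joint additive model at the final
positions.

Genotypes are coded x = +1 for the B (Ct-1-like) and -1 for the A
(Col-0-like) allele, so a reported additive effect is the mean change in the
trait from replacing the A allele by the B allele.  Between markers the
expected coding E[x] = 2 P(B) - 1 is used (Haley--Knott regression), with
P(B) from the selfed-RIL two-locus transition algebra: switch probability
over a cM interval d is R = 2r/(1+2r), r the Haldane fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PhenotypeTable, RILPopulation
from .synthetic import haldane_r, ril_expansion

__all__ = [
    "ScanConfig",
    "LodCurve",
    "QTLResult",
    "genotype_probabilities",
    "interval_mapping",
    "permutation_threshold",
    "mqm_scan",
    "detect_qtl",
    "fit_qtl_model",
    "map_qtl",
]

_LOD_EPS = 1e-12  # floor on RSS1/RSS0, capping LOD on perfect fits


@dataclass(frozen=True)
class ScanConfig:
    """Genome-scan settings: pseudomarker step (cM), permutation count and
    significance level, cofactor exclusion window (cM), support-interval LOD
    drop, and the RNG seed for permutations."""

    step: float = 1.0
    n_permutations: int = 1000
    alpha: float = 0.05
    cofactor_window: float = 10.0
    lod_drop: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not (0 < self.alpha < 0.5):
            raise ValueError("alpha must lie in (0, 0.5)")


@dataclass
class LodCurve:
    """LOD scores on a pseudomarker grid."""

    chrom: np.ndarray     # object array of chromosome labels
    pos_cM: np.ndarray
    lod: np.ndarray

    def __post_init__(self):
        if np.any(self.lod < -1e-9):
            raise ValueError("LOD scores must be >= 0")
        self.lod = np.maximum(self.lod, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chr": self.chrom, "pos_cM": self.pos_cM, "lod": self.lod}
        )

    def max_lod(self) -> float:
        return float(self.lod.max())


@dataclass
class QTLResult:
    """One detected QTL: location, significance, support, effect, R^2 (%)."""

    name: str
    chrom: str
    pos_cM: float
    lod: float
    ci_lo: float
    ci_hi: float
    additive_effect: float | None = None
    r2_pct: float | None = None

    def __post_init__(self):
        if not (self.ci_lo <= self.pos_cM <= self.ci_hi):
            raise ValueError("support interval must contain the peak")


# ---------------------------------------------------------------------------
# genotype probabilities

def _prob_b_at(G: np.ndarray, mpos: np.ndarray, pos: float) -> np.ndarray:
    """P(genotype = B) at ``pos`` for each line, conditional on the nearest
    observed flanking markers (Markov RIL transition algebra)."""
    n, m = G.shape
    out = np.full(n, 0.5)
    jr = int(np.searchsorted(mpos, pos, side="left"))
    for i in range(n):
        row = G[i]
        # nearest observed flank on each side (a marker exactly at pos
        # counts as both)
        jl_i = None
        for j in range(min(jr, m - 1), -1, -1):
            if mpos[j] <= pos + 1e-9 and not np.isnan(row[j]):
                jl_i = j
                break
        jr_i = None
        for j in range(jr, m):
            if mpos[j] >= pos - 1e-9 and not np.isnan(row[j]):
                jr_i = j
                break
        if jl_i is not None and abs(mpos[jl_i] - pos) < 1e-9:
            out[i] = row[jl_i]
            continue
        if jr_i is not None and abs(mpos[jr_i] - pos) < 1e-9:
            out[i] = row[jr_i]
            continue
        if jl_i is None and jr_i is None:
            out[i] = 0.5
            continue
        if jl_i is None or jr_i is None:
            j = jl_i if jl_i is not None else jr_i
            R = float(ril_expansion(haldane_r(abs(pos - mpos[j]))))
            out[i] = (1.0 - R) if row[j] == 1.0 else R
            continue
        RL = float(ril_expansion(haldane_r(pos - mpos[jl_i])))
        RR = float(ril_expansion(haldane_r(mpos[jr_i] - pos)))
        gl, gr = row[jl_i], row[jr_i]
        # T(a, b; R) = R if a != b else 1 - R
        pb = (RL if gl == 0.0 else 1.0 - RL) * (RR if gr == 0.0 else 1.0 - RR)
        pa = ((1.0 - RL) if gl == 0.0 else RL) * ((1.0 - RR) if gr == 0.0 else RR)
        out[i] = pb / (pb + pa)
    return out


def _scan_grid(pop: RILPopulation, step: float):
    """Pseudomarker grid: regular step per chromosome, plus all markers."""
    chroms, positions = [], []
    for chrom in pop.map.chromosomes:
        mpos = pop.map.positions[chrom]
        grid = np.arange(mpos[0], mpos[-1] + step / 2, step)
        grid = np.unique(np.concatenate([grid, mpos]))
        chroms.extend([chrom] * grid.size)
        positions.append(grid)
    return np.array(chroms, dtype=object), np.concatenate(positions)


def genotype_probabilities(pop: RILPopulation, step: float = 1.0):
    """P(B) for every line at every pseudomarker.

    Returns ``(chrom, pos_cM, P)`` with ``P`` of shape n_lines x n_positions.
    """
    chroms, positions = _scan_grid(pop, step)
    P = np.empty((pop.n_lines, positions.size))
    for k, (c, p) in enumerate(zip(chroms, positions)):
        mpos = pop.map.positions[c]
        G = pop.genotypes[pop.map.markers[c]].to_numpy(float)
        P[:, k] = _prob_b_at(G, mpos, float(p))
    return chroms, positions, P


def _align(pop: RILPopulation, phenotype: PhenotypeTable, trait: str | None):
    if trait is None:
        traits = phenotype.records["trait"].unique()
        if len(traits) != 1:
            raise ValueError(f"specify trait; table has {list(traits)}")
        trait = traits[0]
    vals = phenotype.values_for(trait)
    lines = [l for l in pop.line_ids if l in vals.index]
    y = vals.loc[lines].to_numpy(float)
    keep = np.isfinite(y)
    lines = [l for l, k in zip(lines, keep) if k]
    return lines, y[keep]


def _lod_single(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """LOD for simple regression of y on each column of X (plus intercept).

    Uses the identity LOD = -(n/2) log10(1 - r^2) with r the sample
    correlation; constant columns get LOD 0.
    """
    n = y.size
    yc = y - y.mean()
    ny = np.linalg.norm(yc)
    Xc = X - X.mean(axis=0)
    nx = np.linalg.norm(Xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (nx * ny)
    r = np.nan_to_num(r, nan=0.0)
    r2 = np.clip(r**2, 0.0, 1.0 - _LOD_EPS)
    return -(n / 2.0) * np.log10(1.0 - r2)


def interval_mapping(
    pop: RILPopulation,
    phenotype: PhenotypeTable,
    config: ScanConfig = ScanConfig(),
    trait: str | None = None,
) -> LodCurve:
    """Single-QTL genome scan by Haley--Knott regression on E[x] = 2P(B)-1."""
    lines, y = _align(pop, phenotype, trait)
    if len(lines) < 20:
        raise ValueError("interval mapping needs >= 20 phenotyped lines")
    if np.std(y) == 0:
        raise ValueError("constant phenotype")
    sub = RILPopulation(pop.map, pop.genotypes.loc[lines])
    chroms, positions, P = genotype_probabilities(sub, config.step)
    X = 2.0 * P - 1.0
    return LodCurve(chroms, positions, _lod_single(y, X))


def permutation_threshold(
    pop: RILPopulation,
    phenotype: PhenotypeTable,
    config: ScanConfig = ScanConfig(),
    trait: str | None = None,
) -> float:
    """Genome-wide LOD significance threshold by phenotype permutation.

    Shuffles the phenotype over lines ``n_permutations`` times (seeded),
    rescans, and returns the empirical (1 - alpha) quantile of the
    genome-wide maximum LOD.
    """
    lines, y = _align(pop, phenotype, trait)
    sub = RILPopulation(pop.map, pop.genotypes.loc[lines])
    _, _, P = genotype_probabilities(sub, config.step)
    X = 2.0 * P - 1.0
    n = y.size
    Xc = X - X.mean(axis=0)
    nx = np.linalg.norm(Xc, axis=0)
    nx[nx == 0] = np.inf
    rng = np.random.default_rng(config.seed)
    perms = np.array([rng.permutation(y) for _ in range(config.n_permutations)])
    Pc = perms - perms.mean(axis=1, keepdims=True)
    ny = np.linalg.norm(Pc, axis=1)
    ny[ny == 0] = np.inf
    r = (Pc @ Xc) / np.outer(ny, nx)
    r2 = np.clip(r**2, 0.0, 1.0 - _LOD_EPS)
    max_lod = (-(n / 2.0) * np.log10(1.0 - r2)).max(axis=1)
    return float(np.quantile(max_lod, 1.0 - config.alpha))


def _expected_x_at(pop: RILPopulation, lines, chrom: str, pos: float) -> np.ndarray:
    G = pop.genotypes.loc[lines, pop.map.markers[chrom]].to_numpy(float)
    return 2.0 * _prob_b_at(G, pop.map.positions[chrom], float(pos)) - 1.0


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


def mqm_scan(
    pop: RILPopulation,
    phenotype: PhenotypeTable,
    cofactors,
    config: ScanConfig = ScanConfig(),
    trait: str | None = None,
) -> LodCurve:
    """Multiple-QTL scan with marker cofactors controlling the background.

    At each test position the model includes all cofactor markers except
    those within ``cofactor_window`` cM of the test position on the same
    chromosome; the LOD compares the models with and without the
    test-position term.  Exactly collinear cofactors are dropped with a
    warning.  With no cofactors this reduces to interval mapping.
    """
    lines, y = _align(pop, phenotype, trait)
    if np.std(y) == 0:
        raise ValueError("constant phenotype")
    sub = RILPopulation(pop.map, pop.genotypes.loc[lines])
    n = y.size
    # cofactor genotypes as expected +/-1 coding (missing imputed)
    cof_info = []
    for m in cofactors:
        chrom = pop.map.chrom_of(m)
        mpos = pop.map.positions[chrom][pop.map.markers[chrom].index(m)]
        x = _expected_x_at(sub, lines, chrom, mpos)
        cof_info.append((m, chrom, float(mpos), x))
    # drop exactly collinear cofactors
    kept = []
    basis = [np.ones(n)]
    for m, chrom, mpos, x in cof_info:
        trial = np.column_stack(basis + [x])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept.append((m, chrom, mpos, x))
            basis.append(x)
        else:
            warnings.warn(f"dropping collinear cofactor {m}")
    chroms, positions, P = genotype_probabilities(sub, config.step)
    X = 2.0 * P - 1.0
    lod = np.zeros(positions.size)
    for k in range(positions.size):
        inc = [
            x
            for (m, cchrom, cpos, x) in kept
            if not (cchrom == chroms[k] and abs(cpos - positions[k]) < config.cofactor_window)
        ]
        base = np.column_stack([np.ones(n)] + inc)
        full = np.column_stack([base, X[:, k]])
        rss0 = _rss(y, base)
        rss1 = max(_rss(y, full), _LOD_EPS * rss0) if rss0 > 0 else 0.0
        lod[k] = (n / 2.0) * np.log10(rss0 / rss1) if rss0 > 0 else 0.0
    return LodCurve(chroms, positions, np.maximum(lod, 0.0))


def detect_qtl(
    curve: LodCurve, threshold: float, config: ScanConfig = ScanConfig()
) -> list[QTLResult]:
    """Pick significant peaks and their LOD-drop support intervals.

    Local maxima above ``threshold`` count as distinct QTL when they are at
    least 2 x cofactor_window apart or separated by a valley dropping at
    least ``lod_drop`` below the lower peak.  Support intervals are the
    contiguous region within ``lod_drop`` of each peak, clipped at the
    valley between adjacent accepted peaks so intervals never overlap.
    """
    results: list[QTLResult] = []
    for chrom in pd.unique(curve.chrom):
        sel = curve.chrom == chrom
        pos = curve.pos_cM[sel]
        lod = curve.lod[sel]
        order = np.argsort(lod)[::-1]
        accepted: list[int] = []
        for idx in order:
            if lod[idx] < threshold:
                break
            ok = True
            for other in accepted:
                lo, hi = sorted((idx, other))
                valley = lod[lo : hi + 1].min()
                far = abs(pos[idx] - pos[other]) >= 2 * config.cofactor_window
                deep = valley <= min(lod[idx], lod[other]) - config.lod_drop
                higher_nearby = not (far or deep)
                if higher_nearby:
                    ok = False
                    break
            if ok:
                accepted.append(int(idx))
        accepted.sort()
        for j, idx in enumerate(accepted):
            cut = lod[idx] - config.lod_drop
            lo_i = idx
            while lo_i > 0 and lod[lo_i - 1] >= cut:
                lo_i -= 1
            hi_i = idx
            while hi_i < lod.size - 1 and lod[hi_i + 1] >= cut:
                hi_i += 1
            # clip at the valley towards neighbouring accepted peaks
            if j > 0:
                prev = accepted[j - 1]
                valley_i = prev + int(np.argmin(lod[prev : idx + 1]))
                lo_i = max(lo_i, valley_i + 1) if valley_i + 1 <= idx else idx
            if j < len(accepted) - 1:
                nxt = accepted[j + 1]
                valley_i = idx + int(np.argmin(lod[idx : nxt + 1]))
                hi_i = min(hi_i, valley_i - 1) if valley_i - 1 >= idx else idx
            results.append(
                QTLResult(
                    name=f"qtl_{chrom}_{pos[idx]:g}",
                    chrom=str(chrom),
                    pos_cM=float(pos[idx]),
                    lod=float(lod[idx]),
                    ci_lo=float(pos[lo_i]),
                    ci_hi=float(pos[hi_i]),
                )
            )
    return results


def fit_qtl_model(
    pop: RILPopulation,
    phenotype: PhenotypeTable,
    qtl_positions,
    trait: str | None = None,
):
    """Joint additive model at the given (chromosome, position) pairs.

    Returns ``(effects, r2_pct, total_r2_pct)``: the per-QTL additive effect
    (half the difference between fitted B and A class means, i.e. the
    regression coefficient on the +/-1 coding), the per-QTL drop-one
    R-squared in percent, and the model's total R-squared in percent.
    """
    if len(qtl_positions) == 0:
        raise ValueError("need at least one QTL position")
    lines, y = _align(pop, phenotype, trait)
    n = y.size
    cols = [
        _expected_x_at(pop, lines, str(chrom), float(p)) for chrom, p in qtl_positions
    ]
    X = np.column_stack([np.ones(n)] + cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify which QTL columns are mutually collinear
        bad = []
        basis = [np.ones(n)]
        for j, c in enumerate(cols):
            trial = np.column_stack(basis + [c])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                basis.append(c)
            else:
                bad.append(qtl_positions[j])
        raise ValueError(f"collinear QTL positions: {bad}")
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    effects = beta[1:]
    sst = float(((y - y.mean()) ** 2).sum())
    rss_full = _rss(y, X)
    total_r2 = 100.0 * (sst - rss_full) / sst if sst > 0 else 0.0
    r2 = []
    for j in range(len(cols)):
        Xr = np.delete(X, j + 1, axis=1)
        r2.append(100.0 * (_rss(y, Xr) - rss_full) / sst if sst > 0 else 0.0)
    return np.asarray(effects), np.asarray(r2), float(total_r2)


def map_qtl(
    pop: RILPopulation,
    phenotype: PhenotypeTable,
    config: ScanConfig = ScanConfig(),
    trait: str | None = None,
):
    """Full two-pass QTL workflow for one trait.

    IM scan -> permutation threshold -> putative QTL -> MQM with the closest
    marker to each putative peak as cofactor -> final QTL with effects and
    R-squared from the joint model.  Returns a dict with the curves, the
    threshold, and the final ``QTLResult`` list.
    """
    im = interval_mapping(pop, phenotype, config, trait)
    thr = permutation_threshold(pop, phenotype, config, trait)
    putative = detect_qtl(im, thr, config)
    if not putative:
        return {"im": im, "mqm": im, "threshold": thr, "qtl": []}
    cofactors = []
    for q in putative:
        mpos = pop.map.positions[q.chrom]
        names = pop.map.markers[q.chrom]
        cofactors.append(names[int(np.argmin(np.abs(mpos - q.pos_cM)))])
    mqm = mqm_scan(pop, phenotype, cofactors, config, trait)
    final = detect_qtl(mqm, thr, config)
    if not final:
        final = putative
        mqm_used = im
    else:
        mqm_used = mqm
    effects, r2, total_r2 = fit_qtl_model(
        pop, phenotype, [(q.chrom, q.pos_cM) for q in final], trait
    )
    for q, e, r in zip(final, effects, r2):
        q.additive_effect = float(e)
        q.r2_pct = float(r)
    return {
        "im": im,
        "mqm": mqm_used,
        "threshold": thr,
        "qtl": final,
        "total_r2_pct": total_r2,
    }
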