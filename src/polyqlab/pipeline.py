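"""Ensemble-level characterization: descriptor tables, mechanical stability
statistics, knot census, length scans with fits, and sequence utilities.

The per-conformer work (descriptors, structure-based pulling, knot
classification) is orchestrated here into summary tables mirroring how
conformer sets of different chain lengths are compared: the fraction of
mechanically stable conformers chi_F follows a logarithmic law in chain
length while the maximum F_max grows as a power law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from polyqlab.structure import Ensemble
from polyqlab import descriptors as desc
from polyqlab import go_model as go
from polyqlab import knots as knots_mod

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class PipelineConfig:
    """Knobs of the ensemble characterization (defaults are study values)."""

    go_params: go.GoModelParams = field(default_factory=go.GoModelParams)
    n_pull_seeds: int = 5          # pulls per conformer; F_max is their median
    knot_closures: int = 64
    min_separation: int = 3
    hist_range: tuple[float, float] = (0.0, 3.0)   # eps/A
    hist_width: float = 0.2
    n_bootstrap: int = 2000
    seed: int = 0
    classify_knots: bool = True


@dataclass
class EnsembleSummary:
    """Per-conformer descriptor table plus ensemble statistics."""

    table: pd.DataFrame
    zero_peak_fraction: float
    zero_peak_error: float
    knotted_fraction: float
    knotted_error: float
    hist_edges: np.ndarray
    hist_mass: np.ndarray         # probability mass per positive-F_max bin

    @property
    def n_conformers(self) -> int:
        return len(self.table)

    @property
    def chi_F(self) -> float:
        """Fraction of conformers with at least one force peak."""
        return 1.0 - self.zero_peak_fraction


def fraction_with_bootstrap(flags, n_boot: int = 2000, seed: int = 0):
    """Mean of boolean flags with a bootstrap standard error.

    The error is the standard deviation of the mean over ``n_boot``
    resamples with replacement; deterministic per seed.
    """
    flags = np.asarray(flags, dtype=float)
    if flags.size == 0:
        raise ValueError("empty flag list")
    rng = np.random.default_rng(seed)
    n = flags.size
    idx = rng.integers(0, n, size=(n_boot, n))
    means = flags[idx].mean(axis=1)
    return float(flags.mean()), float(means.std())


def median_fmax_pull(model: go.GoModel, params: go.GoModelParams,
                     n_seeds: int):
    """Median F_max (and its run's n_p) over repeated pulls.

    Zero-contact models cannot articulate a force peak, so they report
    (0, 0) without simulation.
    """
    if model.n_contacts == 0:
        return 0.0, 0
    results = []
    for s in range(n_seeds):
        curve, _ = go.pull_constant_speed(
            model, params.with_seed(params.seed + 7919 * s + 13))
        results.append((curve.F_max, curve.n_p))
    results.sort()
    return results[len(results) // 2]


def characterize_ensemble(ensemble: Ensemble,
                          config: PipelineConfig | None = None) -> EnsembleSummary:
    """Run descriptors, pulling and knot classification over an ensemble."""
    config = config or PipelineConfig()
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    lengths = {len(c) for c in ensemble}
    if len(lengths) > 1:
        raise ValueError(f"mixed chain lengths in one ensemble: {lengths}")
    rows = []
    for c in ensemble:
        d = desc.compute_descriptors(c, min_separation=config.min_separation)
        cmap = desc.build_contact_map(
            c if d.contact_mode == "heavy" else _with_backbone(c),
            min_separation=config.min_separation)
        model = go.build_go_model(c, cmap, config.go_params)
        f_max, n_p = median_fmax_pull(model, config.go_params,
                                      config.n_pull_seeds)
        if config.classify_knots:
            ktype, votes = knots_mod.classify_knot(
                c, n_closures=config.knot_closures, seed=config.seed)
            if ktype not in ("0_1", "other"):
                _, _, delta_k = knots_mod.knot_core(
                    c, n_closures=config.knot_closures, seed=config.seed)
            else:
                delta_k = None
        else:
            ktype, votes, delta_k = "0_1", 1.0, None
        rows.append({
            "id": c.id, "N": d.n_residues, "R_g": d.R_g, "w": d.w,
            "ss_alpha": d.ss_alpha, "ss_beta": d.ss_beta,
            "ss_turn": d.ss_turn, "ss_total": d.ss_total,
            "z_mean": d.z_mean, "CO": d.CO,
            "n_contacts": d.n_contacts, "contact_mode": d.contact_mode,
            "volatile": d.volatile, "F_max": f_max, "n_p": n_p,
            "knot_type": ktype, "knot_votes": votes, "delta_k": delta_k,
        })
    table = pd.DataFrame(rows)
    zero_flags = table["F_max"].to_numpy() == 0.0
    knot_flags = (~table["knot_type"].isin(["0_1", "other"])).to_numpy()
    zp, zp_err = fraction_with_bootstrap(zero_flags, config.n_bootstrap,
                                         config.seed)
    kf, kf_err = fraction_with_bootstrap(knot_flags, config.n_bootstrap,
                                         config.seed + 1)
    lo, hi = config.hist_range
    edges = np.arange(lo, hi + config.hist_width / 2, config.hist_width)
    positive = table.loc[table["F_max"] > 0, "F_max"].to_numpy()
    counts, edges = np.histogram(positive, bins=edges)
    mass = counts / len(table)
    return EnsembleSummary(table, zp, zp_err, kf, kf_err, edges, mass)


def _with_backbone(conformer):
    from polyqlab.synthetic import backbone_from_ca
    return backbone_from_ca(conformer)


# ---------------------------------------------------------------------------
# length scan
# ---------------------------------------------------------------------------

@dataclass
class LengthScanRow:
    n: int
    chi_F: float
    fmax_M: float
    mean_Rg: float
    mean_w: float
    knotted_fraction: float


@dataclass
class LengthScanFit:
    """chi_F(n) = a ln(n / b) and fmax_M(n) = c n^d least-squares fits."""

    a: float = np.nan
    b: float = np.nan
    a_err: float = np.nan
    b_err: float = np.nan
    c: float = np.nan
    d: float = np.nan
    c_err: float = np.nan
    d_err: float = np.nan
    chi_converged: bool = False
    fmax_converged: bool = False


def log_law(n, a, b):
    return a * np.log(np.asarray(n, float) / b)


def power_law(n, c, d):
    return c * np.asarray(n, float) ** d


def length_scan(sets: dict[int, EnsembleSummary]):
    """Rows of per-length statistics plus the two cross-length fits."""
    if len(sets) < 3:
        raise ValueError("need at least 3 chain lengths for fitting")
    rows = []
    for n in sorted(sets):
        s = sets[n]
        rows.append(LengthScanRow(
            n=n,
            chi_F=s.chi_F,
            fmax_M=float(s.table["F_max"].max()),
            mean_Rg=float(s.table["R_g"].mean()),
            mean_w=float(s.table["w"].mean()),
            knotted_fraction=s.knotted_fraction,
        ))
    return rows, fit_length_scan(
        np.array([r.n for r in rows], float),
        np.array([r.chi_F for r in rows]),
        np.array([r.fmax_M for r in rows]),
    )


def fit_length_scan(n: np.ndarray, chi_f: np.ndarray,
                    fmax_m: np.ndarray) -> LengthScanFit:
    """Fit the logarithmic chi_F law and the power-law maximum force."""
    fit = LengthScanFit()
    try:
        popt, pcov = curve_fit(log_law, n, chi_f, p0=(0.3, 8.0),
                               bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
                               maxfev=20000)
        fit.a, fit.b = popt
        fit.a_err, fit.b_err = np.sqrt(np.diag(pcov))
        fit.chi_converged = True
    except (RuntimeError, ValueError):
        pass
    try:
        popt, pcov = curve_fit(power_law, n, fmax_m, p0=(0.2, 0.5),
                               maxfev=20000)
        fit.c, fit.d = popt
        fit.c_err, fit.d_err = np.sqrt(np.diag(pcov))
        fit.fmax_converged = True
    except (RuntimeError, ValueError):
        pass
    return fit


# ---------------------------------------------------------------------------
# statistical-independence checks
# ---------------------------------------------------------------------------

def independence_cdf_gap(x, y) -> float:
    """Sup over the sample grid of |F_xy(a, b) - F_x(a) F_y(b)|.

    Small gaps (< 0.1) indicate statistical independence of the two
    descriptors; a comonotone pair reaches at least ~0.25.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("samples must be the same length")
    if len(x) < 20:
        raise ValueError("need at least 20 paired samples")
    n = len(x)
    lx = (x[None, :] <= x[:, None]).astype(np.float32)   # lx[i,k] = x_k <= x_i
    ly = (y[None, :] <= y[:, None]).astype(np.float32)
    joint = lx @ ly.T / n                                 # F_xy on grid
    fx = lx.mean(axis=1)
    fy = ly.mean(axis=1)
    gap = np.abs(joint - fx[:, None] * fy[None, :])
    return float(gap.max())


def correlation_screen(x, y):
    """OLS of y on x: (R^2, slope, slope standard error, p-value)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired samples")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return (float(res.rvalue ** 2), float(res.slope), float(res.stderr),
            float(res.pvalue))


# ---------------------------------------------------------------------------
# homopolymer tracts
# ---------------------------------------------------------------------------

def tract_null_probability(length: int) -> float:
    """Null probability of a specific homopolymer tract of given length.

    Uses the uniform-composition null (1/20)^length: each of the
    ``length`` positions matches a given residue with probability 1/20.
    """
    if length < 1:
        raise ValueError("tract length must be >= 1")
    return (1.0 / 20.0) ** length


def scan_homopolymer_tracts(sequences, min_length: int = 5):
    """Maximal runs of identical residues of at least ``min_length``.

    ``sequences`` is a list of residue strings or (id, string) pairs.
    Returns (sequence id, residue, 1-based start, run length) tuples.
    """
    out = []
    for k, item in enumerate(sequences):
        if isinstance(item, tuple):
            sid, seq = item
        else:
            sid, seq = f"seq_{k + 1}", item
        for pos, ch in enumerate(seq):
            if ch not in AA_ALPHABET:
                raise ValueError(
                    f"{sid}: invalid residue {ch!r} at position {pos + 1}")
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if j - i >= min_length:
                out.append((sid, seq[i], i + 1, j - i))
            i = j
    return out
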