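"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator here is the forward model of the analysis stage that
consumes its output: plasmid-cleavage time courses come from the same
six-compartment kinetic model the fitter inverts, gel lanes apply a known
multiplicative dye bias that the densitometry stage must undo, trans
fluorescence curves follow the saturating exponential whose early slope
the rate estimator measures, melt curves plant a peak at a known Tm, and
toy two-domain trajectories plant a known COM-distance distribution and
exact contact counts.  All generators are deterministic given their seed.

Noise model: truncated Gaussian (clipped at zero), applied on the
corrected-intensity scale where real densitometry noise enters, with
fractions renormalized to sum to 100 afterwards so the constraint the
fitter assumes is preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cis_kinetics
from .cis_kinetics import CleavageParams, InitialState
from .domain_dynamics import BUILTIN_DOMAINS, Trajectory

__all__ = [
    "SynthSpec",
    "gen_timecourse",
    "gen_gel_lanes",
    "gen_dilution_series",
    "gen_fluorescence",
    "gen_melt_curve",
    "gen_trajectory",
    "factors_from_dye_bias",
]

#: Relative GelRed-style signal response per topology (nicked, linear,
#: supercoiled): supercoiled DNA binds the dye less efficiently.  These are
#: the responses whose correction factors are 0.797/0.855/1.74.
DEFAULT_DYE_BIAS = (1.2547, 1.1696, 0.5747)


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for the gel-based generators.

    noise_sd is in percentage points on corrected-scale intensities;
    dye_bias is the per-topology relative signal response (nicked, linear,
    supercoiled); total_signal is arbitrary pixel units per lane.
    """

    seed: int
    time_grid: tuple
    n_replicates: int = 3
    noise_sd: float = 0.0
    dye_bias: tuple = DEFAULT_DYE_BIAS
    total_signal: float = 10000.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_grid, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("time_grid must be non-empty and strictly increasing")
        if t[0] < 0:
            raise ValueError("time_grid must start at >= 0")
        if len(self.dye_bias) != 3 or any(b <= 0 for b in self.dye_bias):
            raise ValueError("dye_bias must be three strictly positive responses")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.total_signal <= 0:
            raise ValueError("total_signal must be positive")

    def times(self) -> np.ndarray:
        return np.asarray(self.time_grid, dtype=float)


def factors_from_dye_bias(dye_bias) -> tuple:
    """Correction factors consistent with a dye-bias triple.

    Uses the same convention as the calibration estimator
    (``factor_i = mean(response)/response_i``), so generated lanes and
    estimated factors invert each other exactly in the noiseless case.
    """
    b = np.asarray(dye_bias, dtype=float)
    f = b.mean() / b
    return tuple(float(x) for x in f)


def gen_timecourse(
    params: CleavageParams,
    init: InitialState,
    spec: SynthSpec,
    variant: str = "mass_conserving",
) -> list:
    """Replicate plasmid-cleavage time courses from the kinetic model.

    Returns one DataFrame per replicate with columns ``replicate, time_s,
    pct_supercoiled, pct_nicked, pct_linear``.  With ``noise_sd = 0`` the
    percentages equal the ODE observables exactly; with noise, Gaussian
    perturbations are added per observable, clipped at zero and
    renormalized to sum to 100 per time point.  The ground-truth
    parameters are recorded in each frame's ``attrs``.
    """
    times = spec.times()
    sim = cis_kinetics.simulate(params, init, times, variant=variant)
    clean = sim[["TotSC", "TotNICK", "LIN"]].to_numpy()
    rng = np.random.default_rng(spec.seed)
    out = []
    for rep in range(1, spec.n_replicates + 1):
        pct = clean.copy()
        if spec.noise_sd > 0:
            pct = pct + rng.normal(0.0, spec.noise_sd, size=pct.shape)
            pct = np.clip(pct, 0.0, None)
            rows = pct.sum(axis=1)
            rows[rows == 0] = 1.0
            pct = 100.0 * pct / rows[:, None]
        df = pd.DataFrame(
            {
                "replicate": rep,
                "time_s": times,
                "pct_supercoiled": pct[:, 0],
                "pct_nicked": pct[:, 1],
                "pct_linear": pct[:, 2],
            }
        )
        df.attrs["ground_truth"] = {
            "ka": params.ka,
            "kb": params.kb,
            "kini": params.kini,
            "kini2": params.kini2,
            "variant": variant,
            "seed": spec.seed,
        }
        out.append(df)
    return out


def gen_gel_lanes(timecourse: pd.DataFrame, spec: SynthSpec) -> pd.DataFrame:
    """Raw gel band intensities for a time course under a known dye bias.

    Raw intensity of topology i is ``total_signal * fraction_i/100 *
    dye_bias_i`` plus optional Gaussian noise (sd ``noise_sd`` percentage
    points on the corrected scale, i.e. scaled by the bias on the raw
    scale).  Negative noisy intensities are clipped to zero; the number of
    clipped cells is flagged in ``attrs["n_clipped"]``.  A round trip
    through the densitometry correction with factors consistent with the
    dye bias recovers the input fractions.
    """
    frac = timecourse[["pct_nicked", "pct_linear", "pct_supercoiled"]].to_numpy(float)
    sums = frac.sum(axis=1)
    if not np.allclose(sums, 100.0, atol=0.5):
        raise ValueError("time-course fractions must sum to 100 per time point")
    bias = np.asarray(spec.dye_bias, dtype=float)
    raw = spec.total_signal * frac / 100.0 * bias
    n_clipped = 0
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd / 100.0 * spec.total_signal, raw.shape)
        raw = raw + noise * bias
        n_clipped = int((raw < 0).sum())
        raw = np.clip(raw, 0.0, None)
    out = pd.DataFrame(
        {
            "replicate": timecourse["replicate"].to_numpy(),
            "time_s": timecourse["time_s"].to_numpy(float),
            "I_nicked": raw[:, 0],
            "I_linear": raw[:, 1],
            "I_supercoiled": raw[:, 2],
        }
    )
    out.attrs["n_clipped"] = n_clipped
    out.attrs["dye_bias"] = tuple(bias)
    return out


def gen_dilution_series(
    dye_bias,
    amounts,
    seed: int = 0,
    noise_sd: float = 0.0,
    response: float = 1000.0,
) -> pd.DataFrame:
    """Calibration dilution series of equal parts of the three topologies.

    Per lane and topology, intensity = ``response * amount * dye_bias_i``
    plus optional Gaussian noise (absolute sd ``noise_sd``, clipped at 0).
    """
    amounts = np.asarray(amounts, dtype=float)
    if amounts.size == 0:
        raise ValueError("amounts must be non-empty")
    if np.any(amounts <= 0):
        raise ValueError("amounts must be strictly positive")
    bias = np.asarray(dye_bias, dtype=float)
    if bias.shape != (3,) or np.any(bias <= 0):
        raise ValueError("dye_bias must be three strictly positive responses")
    ideal = response * amounts[:, None] * bias
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ideal = np.clip(ideal + rng.normal(0.0, noise_sd, ideal.shape), 0.0, None)
    return pd.DataFrame(
        {
            "lane": np.arange(1, amounts.size + 1),
            "amount": amounts,
            "I_nicked": ideal[:, 0],
            "I_linear": ideal[:, 1],
            "I_supercoiled": ideal[:, 2],
        }
    )


def gen_fluorescence(
    rate: float,
    f_max: float,
    background: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
    condition: str = "synthetic",
) -> pd.DataFrame:
    """Saturating trans-cleavage reporter curve.

    ``F(t) = background + f_max * (1 - exp(-rate*t))`` plus optional
    Gaussian noise; monotone non-decreasing when noiseless.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if f_max < 0:
        raise ValueError("f_max must be >= 0")
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    signal = background + f_max * (1.0 - np.exp(-rate * t))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, t.shape)
    df = pd.DataFrame({"time_s": t, "rfu": signal})
    df["condition"] = condition
    df.attrs["ground_truth"] = {"rate": rate, "f_max": f_max, "background": background}
    return df


def gen_melt_curve(
    tm: float,
    width: float,
    shape: str = "peaked",
    amplitude: float = 1000.0,
    baseline: float = 50.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid=None,
) -> pd.DataFrame:
    """Thermal-shift melt curve on the standard 25-99 °C, 1 °C grid.

    ``shape="peaked"`` plants a Gaussian unfolding peak at ``tm`` (the
    global maximum lands on the grid point nearest ``tm``);
    ``shape="monotonic"`` produces a strictly rising trace with no
    interior maximum, emulating a protein with no detectable fluorescence
    peak.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    temp = np.arange(25.0, 100.0) if grid is None else np.asarray(grid, dtype=float)
    if shape == "peaked":
        if not (temp[0] <= tm <= temp[-1]):
            raise ValueError(f"tm={tm} must lie within the grid for a peaked curve")
        fl = baseline + amplitude * np.exp(-0.5 * ((temp - tm) / width) ** 2)
    elif shape == "monotonic":
        fl = baseline + amplitude * (temp - temp[0]) / (temp[-1] - temp[0])
    else:
        raise ValueError(f"unknown shape {shape!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fl = fl + rng.normal(0.0, noise_sd, fl.shape)
    df = pd.DataFrame({"temperature_C": temp, "fluorescence": fl})
    df.attrs["ground_truth"] = {"tm": tm if shape == "peaked" else None, "shape": shape}
    return df


# ---------------------------------------------------------------------------
# toy trajectories

#: Lattice spacing for the rigid atom clouds (Å).  Large enough that a
#: planted atom 3.4 Å from its partner cannot come within 3.5 Å of any
#: other atom of the opposite cloud.
_LATTICE_SPACING = 8.0

#: Planted contacts sit at this distance, strictly inside the 3.5 Å cutoff.
PLANTED_CONTACT_DISTANCE = 3.4


def _lattice_cloud(n: int) -> np.ndarray:
    """First n points of an 8 Å cubic lattice, centred on their centroid."""
    side = max(1, math.ceil(n ** (1.0 / 3.0)))
    pts = []
    for i in range(side + 1):
        for j in range(side + 1):
            for k in range(side + 1):
                pts.append((i, j, k))
                if len(pts) >= n:
                    break
            if len(pts) >= n:
                break
        if len(pts) >= n:
            break
    cloud = np.asarray(pts, dtype=float) * _LATTICE_SPACING
    return cloud - cloud.mean(axis=0)


def gen_trajectory(
    n_frames: int,
    atoms_per_domain: int,
    target_distance_mean: float,
    target_distance_sd: float,
    n_planted_contacts: int = 0,
    seed: int = 0,
    contact_frames=(0,),
    orthologue: str = "FnCas12a",
) -> Trajectory:
    """Toy two-domain trajectory with planted distances and contacts.

    Two rigid carbon clouds on an 8 Å lattice are labelled with the REC2
    and Nuc residue ranges of ``orthologue``.  The per-frame COM
    separation is drawn from Normal(mean, sd), truncated above the cloud
    diameter plus a contact-clearance margin so the clouds can never touch
    accidentally.  In each frame listed in ``contact_frames``, exactly
    ``n_planted_contacts`` atom pairs are placed at 3.4 Å (strictly inside
    the 3.5 Å cutoff); moving those atoms shifts the cloud COM slightly,
    so COM-distance assertions should use ``n_planted_contacts=0``.
    Ground truth is recorded in the returned trajectory's
    ``ground_truth`` attribute.
    """
    if n_frames < 1 or atoms_per_domain < 1:
        raise ValueError("n_frames and atoms_per_domain must be >= 1")
    if target_distance_sd < 0:
        raise ValueError("target_distance_sd must be >= 0")
    if n_planted_contacts > atoms_per_domain:
        raise ValueError(
            f"cannot plant {n_planted_contacts} contacts with only "
            f"{atoms_per_domain} atoms per domain"
        )
    cloud = _lattice_cloud(atoms_per_domain)
    diameter = 0.0
    if atoms_per_domain > 1:
        from scipy.spatial.distance import pdist

        diameter = float(pdist(cloud).max())
    clearance = diameter + 2 * PLANTED_CONTACT_DISTANCE + 1.0
    if target_distance_mean <= clearance and target_distance_sd == 0:
        raise ValueError(
            f"target_distance_mean must exceed the cloud clearance "
            f"({clearance:.1f} Å) when sd=0"
        )
    rng = np.random.default_rng(seed)
    dists = np.empty(n_frames)
    for k in range(n_frames):
        d = rng.normal(target_distance_mean, target_distance_sd)
        while d <= clearance:
            d = rng.normal(target_distance_mean, target_distance_sd)
        dists[k] = d

    rec2_range, nuc_range = (
        BUILTIN_DOMAINS[orthologue]["REC2"],
        BUILTIN_DOMAINS[orthologue]["Nuc"],
    )

    def _res_ids(rng_pair):
        start, end = rng_pair
        span = end - start + 1
        return start + (np.arange(atoms_per_domain) % span)

    coords = np.empty((n_frames, 2 * atoms_per_domain, 3))
    axis = np.array([1.0, 0.0, 0.0])
    contact_frames = set(int(f) for f in contact_frames) if n_planted_contacts else set()
    for k in range(n_frames):
        a = cloud.copy()
        b = cloud + dists[k] * axis
        if k in contact_frames:
            for p in range(n_planted_contacts):
                b[p] = a[p] + PLANTED_CONTACT_DISTANCE * np.array([0.0, 1.0, 0.0])
        coords[k, :atoms_per_domain] = a
        coords[k, atoms_per_domain:] = b
    traj = Trajectory(
        coords=coords,
        res_id=np.concatenate([_res_ids(rec2_range), _res_ids(nuc_range)]),
        element=np.array(["C"] * (2 * atoms_per_domain)),
        atom_name=np.array(["CA"] * (2 * atoms_per_domain)),
        chain_id=np.array(["A"] * atoms_per_domain + ["B"] * atoms_per_domain),
    )
    traj.ground_truth = {
        "distance_mean": target_distance_mean,
        "distance_sd": target_distance_sd,
        "distances": dists,
        "n_planted_contacts": n_planted_contacts,
        "contact_frames": sorted(contact_frames),
        "seed": seed,
        "orthologue": orthologue,
    }
    return traj
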