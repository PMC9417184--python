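"""Small-angle X-ray scattering: theoretical Debye profiles, Guinier
analysis, curve fitting, and oligomeric-state classification.

The theoretical intensity is the orientationally averaged Debye sum

    I(q) = sum_i sum_j f_i f_j sin(q r_ij) / (q r_ij),

with constant per-scatterer form factors (electron counts).  Hydration-layer
and excluded-volume corrections are deliberately not modelled: state
classification among candidate assemblies depends on their shape, which the
vacuum Debye sum captures.  The scattering vector is q = 4 pi sin(theta) /
lambda, in inverse Angstrom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

from .structure import AssemblyModel

QRG_LIMIT = 1.5  # Guinier validity limit q*Rg


@dataclass
class SAXSProfile:
    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be matching 1-D arrays")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma values must be strictly positive")

    def __len__(self) -> int:
        return self.q.size

    # -- 3-column text I/O (q, I[, sigma]; '#' comments) ------------------
    @classmethod
    def read_dat(cls, path: str | Path, label: str = "") -> "SAXSProfile":
        data = np.loadtxt(path, comments="#", ndmin=2)
        if data.shape[1] < 2:
            raise ValueError(f"{path}: expected 2 or 3 whitespace-separated columns")
        sigma = data[:, 2] if data.shape[1] >= 3 else None
        return cls(data[:, 0], data[:, 1], sigma, label or Path(path).stem)

    def write_dat(self, path: str | Path, header: str = "") -> None:
        lines = [f"# {line}" for line in header.splitlines() if line]
        lines.append("# q(A^-1)  I(q)" + ("  sigma" if self.sigma is not None else ""))
        for i in range(len(self)):
            row = f"{self.q[i]:.6e}  {self.intensity[i]:.6e}"
            if self.sigma is not None:
                row += f"  {self.sigma[i]:.6e}"
            lines.append(row)
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Scatterer extraction and the Debye sum
# ---------------------------------------------------------------------------

def _scatterers(model: AssemblyModel, granularity: str) -> tuple[np.ndarray, np.ndarray]:
    """(coords, form factors) at atom or residue granularity.

    Residue granularity places one scatterer per residue at its heavy-atom
    centroid with the residue's total electron count as form factor.
    """
    coords: list[np.ndarray] = []
    factors: list[float] = []
    for chain in model.chains:
        for res in chain.residues:
            heavy = res.heavy_atoms()
            if not heavy:
                continue
            if granularity == "atom":
                for atom in heavy:
                    coords.append(atom.coords)
                    factors.append(atom.electrons)
            elif granularity == "residue":
                coords.append(np.mean([a.coords for a in heavy], axis=0))
                factors.append(sum(a.electrons for a in heavy))
            else:
                raise ValueError(f"unknown granularity {granularity!r}")
    if not coords:
        raise ValueError("model has no heavy atoms")
    return np.vstack(coords), np.asarray(factors, dtype=float)


def debye_profile(model: AssemblyModel, q_grid: np.ndarray,
                  granularity: str = "residue", label: str = "") -> SAXSProfile:
    """Theoretical scattering profile of a model via the Debye sum.

    ``sin(qr)/(qr)`` is evaluated with its q -> 0 limit of 1, so a q grid
    containing 0 is valid and I(0) = (sum f)^2 exactly.
    """
    q = np.asarray(q_grid, dtype=float)
    coords, f = _scatterers(model, granularity)
    d = pdist(coords)                       # condensed pairwise distances
    n = f.size
    iu = np.triu_indices(n, k=1)
    ff = (f[iu[0]] * f[iu[1]])
    self_term = float(np.sum(f ** 2))
    intensity = np.empty_like(q)
    # chunk over q to bound the (nq x npairs) sinc workspace
    chunk = max(1, int(4e6 / max(d.size, 1)))
    for start in range(0, q.size, chunk):
        qs = q[start:start + chunk, None]
        sinc = np.sinc(qs * d[None, :] / np.pi)  # np.sinc(x) = sin(pi x)/(pi x)
        intensity[start:start + chunk] = self_term + 2.0 * (sinc @ ff)
    return SAXSProfile(q, intensity, None, label)


def rg_from_coordinates(model: AssemblyModel, granularity: str = "atom") -> float:
    """Electron-weighted radius of gyration from coordinates."""
    coords, f = _scatterers(model, granularity)
    center = np.average(coords, axis=0, weights=f)
    return float(np.sqrt(np.average(np.sum((coords - center) ** 2, axis=1), weights=f)))


# ---------------------------------------------------------------------------
# Guinier analysis
# ---------------------------------------------------------------------------

@dataclass
class GuinierFit:
    I0: float
    Rg: float
    q_max_used: float
    n_points: int
    r_squared: float

    def to_dict(self) -> dict:
        return {"I0": self.I0, "Rg": self.Rg, "q_max_used": self.q_max_used,
                "n_points": self.n_points, "r_squared": self.r_squared}


def _linear_guinier(q: np.ndarray, intensity: np.ndarray) -> tuple[float, float, float]:
    """Fit ln I = ln I0 - Rg^2 q^2 / 3; returns (I0, Rg, r_squared)."""
    x = q ** 2
    y = np.log(intensity)
    slope, icpt = np.polyfit(x, y, 1)
    if slope >= 0:
        raise ValueError("Guinier fit has non-negative slope: no decaying signal")
    resid = y - (slope * x + icpt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return float(np.exp(icpt)), float(np.sqrt(-3.0 * slope)), r2


def guinier_fit(profile: SAXSProfile, qrg_limit: float = QRG_LIMIT,
                min_points: int = 5, start_points: int = 10) -> GuinierFit:
    """Radius of gyration by the Guinier approximation.

    Deterministic window selection: start from the ``start_points`` lowest-q
    points, shrink until q_max * Rg <= ``qrg_limit``, then grow while the
    refitted window keeps satisfying the limit.
    """
    q, intensity = profile.q, profile.intensity
    n = min(start_points, q.size)
    if n < min_points:
        raise ValueError(f"need at least {min_points} low-q points")
    if np.any(intensity[:n] <= 0):
        raise ValueError("non-positive intensities in the low-q Guinier window")

    I0, rg, r2 = _linear_guinier(q[:n], intensity[:n])
    while q[n - 1] * rg > qrg_limit:
        n -= 1
        if n < min_points:
            raise ValueError(
                f"fewer than {min_points} points satisfy q*Rg <= {qrg_limit}")
        I0, rg, r2 = _linear_guinier(q[:n], intensity[:n])
    while n < q.size and intensity[n] > 0:
        try:
            I0_n, rg_n, r2_n = _linear_guinier(q[:n + 1], intensity[:n + 1])
        except ValueError:
            break
        if q[n] * rg_n > qrg_limit:
            break
        n += 1
        I0, rg, r2 = I0_n, rg_n, r2_n
    return GuinierFit(I0, rg, float(q[n - 1]), n, r2)


# ---------------------------------------------------------------------------
# Curve fitting and classification
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    scale: float
    chi: float
    residuals: np.ndarray
    model_label: str
    q: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {"scale": self.scale, "chi": self.chi, "model_label": self.model_label}


def chi_fit(experimental: SAXSProfile, theoretical: SAXSProfile) -> FitResult:
    """Scale-optimal goodness of fit between experiment and model.

    The scale c minimising sum((I_exp - c I_model)/sigma)^2 has the closed
    form c = sum(w I_e I_m) / sum(w I_m^2), w = 1/sigma^2 (sigma = 1 when
    absent).  chi = sqrt(sum r^2 / (N - 1)).  The theoretical curve is
    linearly interpolated onto the experimental grid; extrapolation is
    forbidden.
    """
    mask = (experimental.q >= theoretical.q[0]) & (experimental.q <= theoretical.q[-1])
    if mask.sum() < 2:
        raise ValueError("experimental and theoretical q ranges do not overlap")
    q = experimental.q[mask]
    i_exp = experimental.intensity[mask]
    sigma = experimental.sigma[mask] if experimental.sigma is not None else np.ones_like(q)
    i_mod = np.interp(q, theoretical.q, theoretical.intensity)
    w = 1.0 / sigma ** 2
    denom = float(np.sum(w * i_mod ** 2))
    if denom <= 0:
        raise ValueError("theoretical intensities vanish on the common grid")
    scale = float(np.sum(w * i_exp * i_mod)) / denom
    residuals = (i_exp - scale * i_mod) / sigma
    chi = float(np.sqrt(np.sum(residuals ** 2) / (residuals.size - 1)))
    return FitResult(scale, chi, residuals, theoretical.label, q)


@dataclass
class OligomericCall:
    best_model: str
    chis: dict[str, float]
    subunit_count: int | None = None
    mass_consistent: bool | None = None
    fits: dict[str, FitResult] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {"best_model": self.best_model,
                "chis": {k: float(v) for k, v in self.chis.items()},
                "subunit_count": self.subunit_count,
                "mass_consistent": self.mass_consistent}


def subunit_count_from_mass(measured_mass_kda: float, subunit_mass_kda: float) -> int:
    """Number of subunits implied by a measured assembly mass."""
    if measured_mass_kda <= 0 or subunit_mass_kda <= 0:
        raise ValueError("masses must be positive")
    return int(round(measured_mass_kda / subunit_mass_kda))


def classify_oligomer(experimental: SAXSProfile,
                      candidates: dict[str, AssemblyModel],
                      measured_mass: float | None = None,
                      subunit_mass: float | None = None,
                      granularity: str = "residue") -> OligomericCall:
    """Pick the candidate assembly whose Debye profile best fits the data.

    Each candidate is scored by ``chi_fit``; the minimum chi wins (first
    label on exact ties).  If masses are given, the implied subunit count is
    checked against the winning model's chain count.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    fits: dict[str, FitResult] = {}
    for label, model in candidates.items():
        model.validate()
        theo = debye_profile(model, experimental.q, granularity, label)
        fits[label] = chi_fit(experimental, theo)
    best = min(fits, key=lambda k: fits[k].chi)
    call = OligomericCall(best, {k: f.chi for k, f in fits.items()}, fits=fits)
    if measured_mass is not None and subunit_mass is not None:
        call.subunit_count = subunit_count_from_mass(measured_mass, subunit_mass)
        call.mass_consistent = (len(candidates[best].chains) == call.subunit_count)
    return call


# ---------------------------------------------------------------------------
# Frame merging
# ---------------------------------------------------------------------------

def merge_frames(frames: list[SAXSProfile], rg_tolerance: float = 0.05,
                 qrg_limit: float = QRG_LIMIT) -> SAXSProfile:
    """Merge elution frames with uniform Rg to reduce noise.

    Keeps the longest contiguous run of frames whose Guinier Rg deviates at
    most ``rg_tolerance`` (fractional) from the run median, then averages
    pointwise; uncertainties shrink as sigma / sqrt(n).
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    q0 = frames[0].q
    for fr in frames[1:]:
        if fr.q.shape != q0.shape or not np.allclose(fr.q, q0):
            raise ValueError("frames are not on a common q grid")
    rgs = np.array([guinier_fit(fr, qrg_limit).Rg for fr in frames])

    best_run: tuple[int, int] | None = None
    for i in range(len(frames)):
        for j in range(i + 1, len(frames)):
            window = rgs[i:j + 1]
            med = float(np.median(window))
            if np.all(np.abs(window - med) <= rg_tolerance * med):
                if best_run is None or (j - i) > (best_run[1] - best_run[0]):
                    best_run = (i, j)
    if best_run is None:
        raise ValueError("no contiguous run of >= 2 frames with uniform Rg")
    i, j = best_run
    kept = frames[i:j + 1]
    n = len(kept)
    intensity = np.mean([fr.intensity for fr in kept], axis=0)
    if all(fr.sigma is not None for fr in kept):
        sigma = np.sqrt(np.sum([fr.sigma ** 2 for fr in kept], axis=0)) / n
    else:
        sigma = np.std([fr.intensity for fr in kept], axis=0, ddof=1) / np.sqrt(n)
        sigma = np.where(sigma > 0, sigma, np.finfo(float).tiny)
    return SAXSProfile(q0, intensity, sigma, label=f"merged[{i}:{j + 1}]")


def classification_report_json(call: OligomericCall, extra: dict | None = None) -> str:
    payload = call.to_dict()
    if extra:
        payload.update(extra)
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
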