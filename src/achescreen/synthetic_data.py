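"""Synthetic generators emulating the statistical structure of screen inputs.

Three generators cover the three upstream data sources the pipeline needs,
so the whole screening-and-validation workflow runs at desk scale:

* :func:`make_library` — a scaffold-clustered compound library.  Members of
  a scaffold share a fingerprint bit-block (pairwise Tanimoto provably above
  a requested floor; cross-scaffold similarity zero) and cluster in
  descriptor space; experimental dG labels are linear in the descriptors
  plus Gaussian noise, so affinity regression has a known ground truth.
* :func:`make_energy_traces` — stationary AR(1) interaction-energy time
  series with prescribed means, marginal standard deviation and
  autocorrelation time (real MD energies are autocorrelated, which is what
  makes SEM calibration an honest test).
* :func:`make_binding_trajectory` — multi-frame receptor/ligand geometries
  with per-residue contact fractions planted by exact frame counts, so
  contact-probability recovery is an equality check rather than a
  statistical one.

Every generator is a pure function of its seed and returns the ground truth
needed for assertions alongside the artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from .chem_library import CompoundRecord, Library
from .lie_energetics import EnergyTrace, LIEParameters, lie_estimate
from .structure_contacts import Frame

__all__ = [
    "LibrarySpec",
    "LibraryTruth",
    "make_library",
    "TraceSpec",
    "make_energy_traces",
    "TrajectorySpec",
    "make_binding_trajectory",
    "make_screening_benchmark",
]


# ---------------------------------------------------------------------------
# Compound libraries

@dataclass(frozen=True)
class LibrarySpec:
    """Shape and ground-truth parameters of a scaffold-clustered library.

    ``coefficients``/``intercept`` define the linear descriptor->dG map
    (kcal/mol); drawn from the seed when ``coefficients`` is None, with norm
    chosen so scaffold-mean affinities spread with sd ~0.75 kcal/mol around
    the intercept.  ``potent_scaffold`` (or the more general
    ``scaffold_dg_overrides``) pins chosen scaffolds' mean dG by shifting
    their descriptor centers along the coefficient direction, keeping labels
    exactly linear in features.
    """

    n_scaffolds: int = 40
    n_per_scaffold: int = 50
    feature_dim: int = 8
    fp_bits: int = 2048
    coefficients: tuple[float, ...] | None = None
    intercept: float = -7.5
    label_noise_sd: float = 0.3
    within_scaffold_min_tanimoto: float = 0.9
    potent_scaffold: tuple[int, float] | None = None  # (index, mean_dg)
    scaffold_dg_overrides: tuple[tuple[int, float], ...] = ()
    center_sd: float = 2.0
    feature_jitter_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.within_scaffold_min_tanimoto <= 1.0:
            raise ValueError("within_scaffold_min_tanimoto must be in (0, 1]")
        if self.label_noise_sd < 0:
            raise ValueError("label_noise_sd must be >= 0")
        if self.n_scaffolds < 1 or self.n_per_scaffold < 1:
            raise ValueError("scaffold counts must be positive")


@dataclass(frozen=True)
class LibraryTruth:
    """Ground truth returned with a generated library."""

    coefficients: np.ndarray
    intercept: float
    scaffold_of: dict[str, int]
    centers: np.ndarray
    scaffold_mean_dg: np.ndarray
    k_flips: int

    def members(self, scaffold: int) -> list[str]:
        return sorted(cid for cid, s in self.scaffold_of.items() if s == scaffold)


def _flip_budget(mask_weight: int, floor: float) -> int:
    """Largest k with (w - 2k) / (w + 2k) >= floor (worst-case pairwise)."""
    # epsilon guards the exact-boundary case against float rounding
    return int(math.floor(mask_weight * (1.0 - floor) / (2.0 * (1.0 + floor)) + 1e-9))


def make_library(spec: LibrarySpec) -> tuple[Library, LibraryTruth]:
    """Generate a scaffold-clustered library with descriptor-linked labels.

    Fingerprints: each scaffold owns a disjoint block of ``fp_bits //
    n_scaffolds`` bits; the scaffold mask sets 3/4 of its block, and each
    member flips exactly ``k`` block bits, with ``k`` derived analytically
    so every within-scaffold pair has Tanimoto >= the requested floor.
    Raises if the block is too small to allow a single flip at that floor.
    """
    rng = np.random.default_rng(spec.seed)
    block = spec.fp_bits // spec.n_scaffolds
    w = max(1, (3 * block) // 4)
    k = _flip_budget(w, spec.within_scaffold_min_tanimoto)
    if k < 1:
        raise ValueError(
            f"fp_bits={spec.fp_bits} too small for Tanimoto floor "
            f"{spec.within_scaffold_min_tanimoto} with {spec.n_scaffolds} "
            f"scaffolds: mask weight w={w} allows k = floor(w(1-f)/(2(1+f))) = "
            f"{k} bit flips; need k >= 1"
        )

    if spec.coefficients is None:
        raw = rng.standard_normal(spec.feature_dim)
        coeffs = raw / np.linalg.norm(raw) * (0.75 / spec.center_sd)
    else:
        coeffs = np.asarray(spec.coefficients, dtype=float)
        if coeffs.size != spec.feature_dim:
            raise ValueError("coefficients length != feature_dim")

    centers = rng.normal(0.0, spec.center_sd, size=(spec.n_scaffolds, spec.feature_dim))
    overrides = dict(spec.scaffold_dg_overrides)
    if spec.potent_scaffold is not None:
        overrides[spec.potent_scaffold[0]] = spec.potent_scaffold[1]
    c_norm2 = float(coeffs @ coeffs)
    for s_idx, target in overrides.items():
        current = float(coeffs @ centers[s_idx] + spec.intercept)
        centers[s_idx] += coeffs * (target - current) / c_norm2

    records: list[CompoundRecord] = []
    scaffold_of: dict[str, int] = {}
    width = len(str(spec.n_scaffolds * spec.n_per_scaffold))
    counter = 0
    for s in range(spec.n_scaffolds):
        mask = np.zeros(spec.fp_bits, dtype=bool)
        block_bits = np.arange(s * block, s * block + block)
        mask[rng.choice(block_bits, size=w, replace=False)] = True
        for _m in range(spec.n_per_scaffold):
            counter += 1
            cid = f"SYN{counter:0{width}d}"
            fp = mask.copy()
            flip = rng.choice(block_bits, size=k, replace=False)
            fp[flip] = ~fp[flip]
            feats = centers[s] + rng.normal(
                0.0, spec.feature_jitter_sd, size=spec.feature_dim
            )
            dg = float(coeffs @ feats + spec.intercept)
            if spec.label_noise_sd > 0:
                dg += float(rng.normal(0.0, spec.label_noise_sd))
            records.append(
                CompoundRecord(id=cid, features=feats, fingerprint=fp, dg_exp=dg)
            )
            scaffold_of[cid] = s

    truth = LibraryTruth(
        coefficients=coeffs,
        intercept=spec.intercept,
        scaffold_of=scaffold_of,
        centers=centers,
        scaffold_mean_dg=centers @ coeffs + spec.intercept,
        k_flips=k,
    )
    return Library(records), truth


# ---------------------------------------------------------------------------
# Interaction-energy traces

@dataclass(frozen=True)
class TraceSpec:
    """Stationary AR(1) energy traces with prescribed moments.

    ``means`` holds the true stationary means (vdw_bound, cou_bound,
    vdw_unbound, cou_unbound) in kcal/mol.  ``autocorr_time`` is the
    exponential autocorrelation time tau in ps; the lag-1 autocorrelation of
    the generated series is exp(-dt/tau).
    """

    means: tuple[float, float, float, float] = (-40.0, -30.898, -22.0, -30.0)
    marginal_sd: float = 3.0
    autocorr_time: float = 10.0
    n_frames: int = 25_000
    dt: float = 2.0
    n_replicas: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marginal_sd < 0:
            raise ValueError("marginal_sd must be >= 0")
        if self.dt <= 0 or self.autocorr_time <= 0:
            raise ValueError("dt and autocorr_time must be positive")
        if self.n_frames < 2 or self.n_replicas < 1:
            raise ValueError("need n_frames >= 2 and n_replicas >= 1")


def _ar1(rng: np.random.Generator, mean: float, sd: float, phi: float, n: int) -> np.ndarray:
    """Stationary AR(1) series with given marginal mean/sd and lag-1 phi."""
    if sd == 0:
        return np.full(n, mean)
    from scipy.signal import lfilter

    eps = rng.standard_normal(n)
    innov_sd = math.sqrt(1.0 - phi * phi)
    z0 = rng.standard_normal()
    z = np.empty(n)
    # direct-form recursion via lfilter with the stationary initial state
    z, _ = lfilter([innov_sd], [1.0, -phi], eps, zi=np.array([phi * z0]))
    return mean + sd * z


def make_energy_traces(
    spec: TraceSpec, params: LIEParameters = LIEParameters()
) -> tuple[list[EnergyTrace], float]:
    """Generate bound/unbound replica traces plus the analytic LIE dG.

    The returned dG is :func:`lie_estimate` applied to the *true* stationary
    means — the value an infinitely long simulation would recover.
    """
    rng = np.random.default_rng(spec.seed)
    phi = math.exp(-spec.dt / spec.autocorr_time)
    times = np.arange(spec.n_frames) * spec.dt
    vdw_b, cou_b, vdw_u, cou_u = spec.means
    traces: list[EnergyTrace] = []
    for rep in range(1, spec.n_replicas + 1):
        for state, (mv, mc) in (("bound", (vdw_b, cou_b)), ("unbound", (vdw_u, cou_u))):
            traces.append(
                EnergyTrace(
                    times=times,
                    v_vdw=_ar1(rng, mv, spec.marginal_sd, phi, spec.n_frames),
                    v_cou=_ar1(rng, mc, spec.marginal_sd, phi, spec.n_frames),
                    state=state,
                    replica=rep,
                )
            )
    dg_true = lie_estimate((vdw_b, cou_b), (vdw_u, cou_u), params)
    return traces, dg_true


# ---------------------------------------------------------------------------
# Contact trajectories

@dataclass(frozen=True)
class TrajectorySpec:
    """Planted per-residue contact fractions for a toy receptor/ligand system.

    ``residue_plan`` lists (residue_id, hb_fraction, sc_fraction).  Because
    a qualifying hydrogen bond necessarily places a ligand heavy atom within
    the heavy-atom contact cutoff of the donor residue, hydrogen-bond frames
    are planted as a subset of contact frames; hb_fraction <= sc_fraction is
    therefore required.
    """

    n_frames: int = 100
    residue_plan: tuple[tuple[int, float, float], ...] = ((1, 0.3, 0.6),)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for rid, hb, sc in self.residue_plan:
            if not (0.0 <= hb <= 1.0 and 0.0 <= sc <= 1.0):
                raise ValueError(f"fractions for residue {rid} must be in [0, 1]")
            if hb > sc:
                raise ValueError(
                    f"residue {rid}: hb_fraction {hb} > sc_fraction {sc}; a "
                    "hydrogen bond implies a heavy-atom contact, so the HB "
                    "fraction cannot exceed the SC fraction"
                )


_RESNAMES = ("TYR", "GLU", "PHE", "SER", "THR", "ASN", "GLN", "LYS", "ARG", "TRP")

# Template geometry per residue, relative to the residue base point.
_HB_IN = np.array([2.9, 0.0, 0.0])    # acceptor collinear with D-H -> 180 deg
_HB_OUT = np.array([14.0, 0.0, 0.0])
_SC_IN = np.array([0.0, 4.0, 0.0])    # 4.0 A from the CB probe at (0, 8, 0)
_SC_OUT = np.array([0.0, 16.0, 0.0])
_RESIDUE_SPACING = 30.0


def make_binding_trajectory(
    spec: TrajectorySpec,
) -> tuple[list[Frame], dict[int, tuple[float, float]]]:
    """Build frames with exact-count planted HB/SC contacts per residue.

    Each residue i sits at (30*i, 0, 0) with a donor N, its hydrogen, and a
    CB heavy-atom probe; the ligand carries one acceptor oxygen and one
    carbon probe per residue.  For each residue exactly
    round(fraction * n_frames) frames place the corresponding ligand atom in
    qualifying geometry (HB: collinear N-H...O at 2.9 A; SC: heavy pair at
    4.0 A); all other frames park it beyond 6 A.  Frame membership is a
    seeded shuffle; HB frames are a subset of SC frames.

    Returns the frames and {residue_id: (hb_fraction, sc_fraction)} with the
    exactly planted fractions.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    plan = list(spec.residue_plan)

    elements, names, resnames, resids, chains, lig_mask = [], [], [], [], [], []
    for j, (rid, _hb, _sc) in enumerate(plan):
        rname = _RESNAMES[j % len(_RESNAMES)]
        for el, nm in (("N", "N"), ("H", "H"), ("C", "CB")):
            elements.append(el)
            names.append(nm)
            resnames.append(rname)
            resids.append(rid)
            chains.append("A")
            lig_mask.append(False)
    for j, (rid, _hb, _sc) in enumerate(plan):
        for el, nm in (("O", f"O{j + 1}"), ("C", f"C{j + 1}")):
            elements.append(el)
            names.append(nm)
            resnames.append("LIG")
            resids.append(9999)
            chains.append("L")
            lig_mask.append(True)

    sc_sets, hb_sets = [], []
    truth: dict[int, tuple[float, float]] = {}
    for rid, hb_frac, sc_frac in plan:
        n_sc = int(np.rint(sc_frac * n))
        n_hb = min(int(np.rint(hb_frac * n)), n_sc)
        order = rng.permutation(n)
        sc_sets.append(set(order[:n_sc].tolist()))
        hb_sets.append(set(order[:n_hb].tolist()))
        truth[rid] = (n_hb / n, n_sc / n)

    frames: list[Frame] = []
    n_res = len(plan)
    for f in range(n):
        coords = np.zeros((3 * n_res + 2 * n_res, 3))
        for j in range(n_res):
            base = np.array([_RESIDUE_SPACING * j, 0.0, 0.0])
            coords[3 * j + 0] = base                        # N (donor)
            coords[3 * j + 1] = base + [1.0, 0.0, 0.0]      # H
            coords[3 * j + 2] = base + [0.0, 8.0, 0.0]      # CB probe
        for j in range(n_res):
            base = np.array([_RESIDUE_SPACING * j, 0.0, 0.0])
            o_idx = 3 * n_res + 2 * j
            coords[o_idx] = base + (_HB_IN if f in hb_sets[j] else _HB_OUT)
            coords[o_idx + 1] = base + (_SC_IN if f in sc_sets[j] else _SC_OUT)
        frames.append(
            Frame(
                coordinates=coords,
                elements=np.array(elements, dtype=object),
                atom_names=np.array(names, dtype=object),
                residue_names=np.array(resnames, dtype=object),
                residue_ids=np.array(resids, dtype=int),
                chains=np.array(chains, dtype=object),
                ligand_mask=np.array(lig_mask, dtype=bool),
            )
        )
    return frames, truth


# ---------------------------------------------------------------------------
# The composite screening benchmark

def make_screening_benchmark(
    seed: int = 0,
    n_scaffolds: int = 40,
    n_per_scaffold: int = 50,
    n_initial_per_scaffold: int = 5,
    potent_mean_dg: float = -11.0,
    mid_mean_dg: float = -10.3,
    label_noise_sd: float = 0.3,
) -> dict:
    """A planted-enrichment world: search library, initial subset, ground truth.

    One scaffold is planted potent (mean dG ``potent_mean_dg``) and one at an
    intermediate tier (``mid_mean_dg``); the remaining scaffold means scatter
    around -7.5 kcal/mol.  The potency gradient is what makes round-wise
    enrichment detectable: the intermediate tier seeds the first similarity
    round together with the potent scaffold, while the second round's top-k
    seeds come from the potent scaffold alone, so the final round's
    distribution concentrates on the strongest binders.

    Returns a dict with the full ``library`` (database stand-in), the
    ``initial`` sub-library (diversity-set stand-in, ``n_initial_per_scaffold``
    per scaffold), the generator ``truth``, and the planted scaffold indices.
    """
    rng = np.random.default_rng(seed)
    potent_idx = 0
    mid_idx = 1
    spec = LibrarySpec(
        n_scaffolds=n_scaffolds,
        n_per_scaffold=n_per_scaffold,
        label_noise_sd=label_noise_sd,
        scaffold_dg_overrides=((potent_idx, potent_mean_dg), (mid_idx, mid_mean_dg)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    library, truth = make_library(spec)
    initial_records = []
    for s in range(n_scaffolds):
        members = truth.members(s)
        chosen = rng.choice(len(members), size=min(n_initial_per_scaffold, len(members)),
                            replace=False)
        initial_records.extend(library[members[i]] for i in sorted(chosen))
    return {
        "library": library,
        "initial": Library(initial_records),
        "truth": truth,
        "potent_scaffold": potent_idx,
        "mid_scaffold": mid_idx,
    }


def make_training_library(
    seed: int,
    truth: LibraryTruth,
    n_scaffolds: int = 31,
    n_per_scaffold: int = 46,
    label_noise_sd: float = 0.3,
) -> Library:
    """A training-set stand-in sharing the benchmark's descriptor->dG map.

    Defaults give 1426 compounds, the scale of a curated inhibition-constant
    collection used to fit the affinity model.
    """
    spec = LibrarySpec(
        n_scaffolds=n_scaffolds,
        n_per_scaffold=n_per_scaffold,
        coefficients=tuple(truth.coefficients.tolist()),
        intercept=truth.intercept,
        label_noise_sd=label_noise_sd,
        seed=seed,
    )
    library, _ = make_library(spec)
    return library
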