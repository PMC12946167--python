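"""Synthetic longitudinal PBMC cohort generator.

Emulates the statistical structure the downstream analyses assume, so the
whole pipeline is testable without controlled-access patient data:

* three survival groups (control arm n=5; LITT patients below median OS n=5
  and above median OS n=7) sampled at four protocol visits (pre-procedure,
  cycles 1, 2 and 4);
* gamma-Poisson (negative binomial) UMI counts with log-normally varying
  library sizes, cell-type marker programs, and an "activated" non-classical
  monocyte subcluster that appears only post-procedure in LITT patients and
  carries the programmed differential-expression signal;
* CD8+ T-cell subtype dynamics driven by per-group row-stochastic transition
  matrices applied to clone-level subtype "homes", so both optimal-transport
  mass flows and clone-fate tables can recover the programmed flows;
* TCRbeta clonotypes drawn from a Dirichlet-multinomial whose concentration
  shrinks after cycle 1 in the long-surviving group (clonal expansion);
* exponential overall survival whose hazard is scaled by a per-patient
  latent signature activity to induce a chosen true hazard ratio, with
  administrative censoring.

Everything is reproducible from ``SimConfig.seed``; :func:`ground_truth`
exposes the programmed (noise-free) quantities for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import (
    CD8_SUBTYPES,
    TIMEPOINT_ORDER,
    CohortDataset,
    SurvivalGroup,
)
from .errors import ConfigError

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort", "ground_truth", "default_transitions"]

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Major cell-type composition of a PBMC sample (fractions sum to 1).
CELL_TYPES: dict[str, float] = {
    "CD8_T": 0.35,
    "CD4_T": 0.20,
    "B": 0.10,
    "NK": 0.10,
    "classical_monocyte": 0.15,
    "non_classical_monocyte": 0.10,
}

#: Initial CD8 subtype distribution at the first sampled visit
#: (central-memory dominant, as in a pre-treatment repertoire).
SUBTYPE_INITIAL = np.array([0.50, 0.10, 0.10, 0.10, 0.05, 0.05, 0.10])

_GROUPS = (
    SurvivalGroup.NLS_PEM.value,
    SurvivalGroup.LITT_LT_MOS.value,
    SurvivalGroup.LITT_GT_MOS.value,
)


def default_transitions() -> dict[str, np.ndarray]:
    """Per-group CD8 subtype transition matrices (rows: source subtype).

    Control arm cells keep their state; short survivors drift from central
    memory and effector states into exhaustion; long survivors convert 60% of
    central-memory mass into effectors at each step.
    """
    idx = {s: i for i, s in enumerate(CD8_SUBTYPES)}
    n = len(CD8_SUBTYPES)
    nls = np.eye(n)
    lt = np.eye(n)
    lt[idx["CD8_CM"]] = 0.0
    lt[idx["CD8_CM"], idx["CD8_CM"]] = 0.5
    lt[idx["CD8_CM"], idx["CD8_EXH"]] = 0.5
    lt[idx["CD8_EFF"]] = 0.0
    lt[idx["CD8_EFF"], idx["CD8_EFF"]] = 0.7
    lt[idx["CD8_EFF"], idx["CD8_EXH"]] = 0.3
    gt = np.eye(n)
    gt[idx["CD8_CM"]] = 0.0
    gt[idx["CD8_CM"], idx["CD8_CM"]] = 0.4
    gt[idx["CD8_CM"], idx["CD8_EFF"]] = 0.6
    return {
        SurvivalGroup.NLS_PEM.value: nls,
        SurvivalGroup.LITT_LT_MOS.value: lt,
        SurvivalGroup.LITT_GT_MOS.value: gt,
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults encode the study design: 5 control, 5 short-surviving and 7
    long-surviving LITT patients at visits PRE, C1, C2 and C4; 2000 genes;
    500 cells per patient and visit; 5% of genes differentially expressed at
    log2 fold-change 1.5 in the activated monocyte subcluster.
    """

    n_patients_per_group: tuple[int, int, int] = (5, 5, 7)
    timepoints: tuple[str, ...] = ("PRE", "C1", "C2", "C4")
    n_genes: int = 2000
    n_cells_per_patient_timepoint: int = 500
    nb_dispersion: float = 0.1
    de_gene_fraction: float = 0.05
    de_log2fc: float = 1.5
    transition_matrix_per_group: Mapping[str, np.ndarray] | None = None
    clonal_expansion_strength: float = 9.0
    survival_hr_true: float = 0.3
    seed: int = 0
    # secondary knobs (stated world; change only deliberately)
    mean_library_size: float = 1500.0
    library_size_sigma: float = 0.35
    marker_fold: float = 6.0
    n_clones_per_patient: int = 150
    clone_concentration: float = 1.0
    activated_fraction_base: float = 0.3
    activated_fraction_slope: float = 0.5
    baseline_hazard_per_month: float = np.log(2) / 8.0
    censor_horizon_months: float = 36.0

    def __post_init__(self) -> None:
        if len(self.n_patients_per_group) != 3 or any(
            int(n) <= 0 for n in self.n_patients_per_group
        ):
            raise ConfigError("n_patients_per_group must be three positive integers")
        unknown = set(self.timepoints) - set(TIMEPOINT_ORDER)
        if unknown:
            raise ConfigError(f"unknown timepoint(s) {sorted(unknown)}")
        if len(self.timepoints) < 2:
            raise ConfigError("need at least two timepoints")
        order = {tp: i for i, tp in enumerate(TIMEPOINT_ORDER)}
        if list(self.timepoints) != sorted(self.timepoints, key=order.__getitem__):
            raise ConfigError("timepoints must be in protocol order")
        for name, value in (
            ("n_genes", self.n_genes),
            ("n_cells_per_patient_timepoint", self.n_cells_per_patient_timepoint),
            ("nb_dispersion", self.nb_dispersion),
            ("survival_hr_true", self.survival_hr_true),
        ):
            if value <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.de_gene_fraction < 1:
            raise ConfigError("de_gene_fraction must lie in (0, 1)")
        if self.clonal_expansion_strength < 0:
            raise ConfigError("clonal_expansion_strength must be >= 0")
        mats = self.transition_matrix_per_group
        if mats is None:
            mats = default_transitions()
        k = len(CD8_SUBTYPES)
        n_pairs = len(self.timepoints) - 1
        normalized: dict[str, list[np.ndarray]] = {}
        for group in _GROUPS:
            if group not in mats:
                raise ConfigError(f"missing transition matrix for group {group}")
            entry = mats[group]
            per_pair = (
                [np.asarray(m, dtype=float) for m in entry]
                if isinstance(entry, (list, tuple))
                else [np.asarray(entry, dtype=float)] * n_pairs
            )
            if len(per_pair) != n_pairs:
                raise ConfigError(
                    f"group {group}: {len(per_pair)} transition matrices for "
                    f"{n_pairs} consecutive timepoint pairs"
                )
            for m in per_pair:
                if m.shape != (k, k):
                    raise ConfigError(f"transition matrices must be {k}x{k}")
                if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-8):
                    raise ConfigError(f"group {group}: transition matrix not row-stochastic")
            normalized[group] = per_pair
        self.transition_matrix_per_group = normalized


@dataclass
class GroundTruth:
    """Programmed (noise-free) quantities behind one :class:`SimConfig`."""

    de_genes: list[str]
    transition_matrices: dict[str, list[np.ndarray]]
    activity: dict[str, float]  # patient -> latent signature activity in [0, 1]
    hr: float
    patients: pd.DataFrame  # patient, group, arm, activity
    subtype_initial: np.ndarray = field(default_factory=lambda: SUBTYPE_INITIAL.copy())


# ---------------------------------------------------------------------------
# deterministic structure (identical across seeds)
# ---------------------------------------------------------------------------


def _patient_frame(config: SimConfig) -> pd.DataFrame:
    rows = []
    prefixes = {"NLS_PEM": "NLS", "LITT_LT_MOS": "LT", "LITT_GT_MOS": "GT"}
    for group, n in zip(_GROUPS, config.n_patients_per_group):
        arm = "NLS_PEM" if group == "NLS_PEM" else "LITT_PEM"
        for i in range(int(n)):
            rows.append(
                {"patient": f"{prefixes[group]}{i + 1:02d}", "group": group, "arm": arm}
            )
    return pd.DataFrame(rows)


def _activities(config: SimConfig) -> pd.DataFrame:
    """Latent signature activity: evenly spaced within group-specific bands.

    Control patients sit near zero, short survivors in a low band and long
    survivors in a high band, so signature strength and survival are linked
    without further randomness (the structure is seed-invariant).
    """
    bands = {"NLS_PEM": (0.0, 0.15), "LITT_LT_MOS": (0.25, 0.45), "LITT_GT_MOS": (0.75, 1.0)}
    patients = _patient_frame(config)
    acts = []
    for group in _GROUPS:
        lo, hi = bands[group]
        n = int((patients["group"] == group).sum())
        acts.extend(np.linspace(lo, hi, n).tolist())
    patients["activity"] = acts
    return patients


def _gene_architecture(config: SimConfig) -> dict[str, np.ndarray]:
    """Deterministic allocation of marker and DE gene indices.

    Gene ids are ``G0000..``; cell-type markers, CD8-subtype markers and the
    DE program occupy disjoint leading blocks (sizes shrink gracefully for
    tiny gene spaces used in fast tests).
    """
    g = config.n_genes
    n_types = len(CELL_TYPES)
    n_sub = len(CD8_SUBTYPES)
    per_type = max(1, min(25, g // (4 * n_types)))
    per_sub = max(1, min(30, g // (4 * n_sub)))
    n_de = max(1, round(config.de_gene_fraction * g))
    cursor = 0
    type_markers = {}
    for ct in CELL_TYPES:
        type_markers[ct] = np.arange(cursor, min(cursor + per_type, g))
        cursor = min(cursor + per_type, g)
    sub_markers = {}
    for st in CD8_SUBTYPES:
        sub_markers[st] = np.arange(cursor, min(cursor + per_sub, g))
        cursor = min(cursor + per_sub, g)
    if cursor + n_de > g:
        raise ConfigError(
            f"n_genes={g} too small for {n_de} DE genes plus marker blocks ({cursor} used)"
        )
    de_idx = np.arange(g - n_de, g)  # trailing block, never overlaps markers
    return {"type_markers": type_markers, "sub_markers": sub_markers, "de_idx": de_idx}


def ground_truth(config: SimConfig) -> GroundTruth:
    """Programmed effects for recovery tests; deterministic given the config."""
    arch = _gene_architecture(config)
    patients = _activities(config)
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    return GroundTruth(
        de_genes=[gene_ids[i] for i in arch["de_idx"]],
        transition_matrices={
            g: [m.copy() for m in ms] for g, ms in config.transition_matrix_per_group.items()
        },
        activity=dict(zip(patients["patient"], patients["activity"])),
        hr=config.survival_hr_true,
        patients=patients,
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _expression_profiles(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Relative-abundance profile (sums to 1) per cell state."""
    arch = _gene_architecture(config)
    base = rng.lognormal(0.0, 1.2, config.n_genes)
    profiles: dict[str, np.ndarray] = {}
    for ct, markers in arch["type_markers"].items():
        prof = base.copy()
        prof[markers] *= config.marker_fold
        profiles[ct] = prof / prof.sum()
    for st, markers in arch["sub_markers"].items():
        prof = base.copy()
        prof[arch["type_markers"]["CD8_T"]] *= config.marker_fold
        prof[markers] *= config.marker_fold
        profiles[st] = prof / prof.sum()
    ncm = base.copy()
    ncm[arch["type_markers"]["non_classical_monocyte"]] *= config.marker_fold
    act = ncm.copy()
    act[arch["de_idx"]] *= 2.0 ** config.de_log2fc
    profiles["non_classical_monocyte"] = ncm / ncm.sum()
    profiles["NCM_activated"] = act / act.sum()
    return profiles


def _rounded_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of total*fractions to integers summing to total."""
    raw = np.asarray(fractions, dtype=float) * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def _random_cdr3(rng: np.random.Generator, n: int) -> list[str]:
    out = []
    for _ in range(n):
        length = int(rng.integers(8, 17))
        core = "".join(_AA[i] for i in rng.integers(0, len(_AA), length))
        out.append(f"C{core}F")
    return out


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_cohort(config: SimConfig) -> CohortDataset:
    """Draw one synthetic cohort; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    truth = ground_truth(config)
    profiles = _expression_profiles(config, rng)
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    patients = truth.patients
    timepoints = list(config.timepoints)
    n_cells = config.n_cells_per_patient_timepoint
    sub_idx = {s: i for i, s in enumerate(CD8_SUBTYPES)}

    # per-patient clone pools: ids, CDR3s, and a subtype "home" chain evolving
    # by the group's transition matrices, so clone fates mirror the mass flows
    clone_info: dict[str, dict[str, np.ndarray | list[str]]] = {}
    for _, prow in patients.iterrows():
        n_clones = config.n_clones_per_patient
        homes = np.empty((len(timepoints), n_clones), dtype=int)
        homes[0] = rng.choice(len(CD8_SUBTYPES), size=n_clones, p=SUBTYPE_INITIAL)
        mats = config.transition_matrix_per_group[prow["group"]]
        for t in range(1, len(timepoints)):
            m = mats[t - 1]
            homes[t] = [rng.choice(len(CD8_SUBTYPES), p=m[h]) for h in homes[t - 1]]
        # persistent repertoire: one base weight draw per patient; clonal
        # expansion replaces it with a lower-concentration (more uneven) draw
        w_base = rng.dirichlet(np.full(n_clones, config.clone_concentration))
        w_expanded = rng.dirichlet(
            np.full(
                n_clones,
                config.clone_concentration / (1.0 + config.clonal_expansion_strength),
            )
        )
        clone_info[prow["patient"]] = {
            "cdr3": _random_cdr3(rng, n_clones),
            "homes": homes,
            "cdr3_cd4": _random_cdr3(rng, n_clones),
            "w_base": w_base,
            "w_expanded": w_expanded,
            "w_cd4": rng.dirichlet(np.full(n_clones, 2.0)),
        }

    blocks: list[sp.csr_matrix] = []
    meta_rows: list[pd.DataFrame] = []
    clono_rows: list[pd.DataFrame] = []
    centers = _blob_centers()

    # programmed subtype distribution chain per group
    subtype_chain: dict[str, list[np.ndarray]] = {}
    for group, mats in config.transition_matrix_per_group.items():
        chain = [SUBTYPE_INITIAL.copy()]
        for m in mats:
            chain.append(chain[-1] @ m)
        subtype_chain[group] = chain

    for _, prow in patients.iterrows():
        patient, group = prow["patient"], prow["group"]
        activity = float(prow["activity"])
        info = clone_info[patient]
        for t, tp in enumerate(timepoints):
            type_counts = _rounded_counts(
                np.array(list(CELL_TYPES.values())), n_cells
            )
            states: list[str] = []
            cell_types: list[str] = []
            subclusters: list[str] = []
            clone_of_cell: list[int] = []  # -1 for non-CD8
            for (ct, _), k in zip(CELL_TYPES.items(), type_counts):
                if k == 0:
                    continue
                if ct == "CD8_T":
                    expanded = (
                        group == "LITT_GT_MOS"
                        and tp not in ("PRE", "C1")
                        and config.clonal_expansion_strength > 0
                    )
                    weights = info["w_expanded"] if expanded else info["w_base"]
                    # subtype composition is the deterministic programmed
                    # chain (largest-remainder rounding), so transition mass
                    # flows are recoverable at their stated values; clones
                    # are then drawn conditionally on the cell's state so
                    # clone fates follow the matrix rows too
                    pi_t = subtype_chain[group][t]
                    n_per_sub = _rounded_counts(pi_t, k)
                    m_t = None if t == 0 else config.transition_matrix_per_group[group][t - 1]
                    homes_prev = info["homes"][max(t - 1, 0)]
                    for s_id, n_s in enumerate(n_per_sub):
                        if n_s == 0:
                            continue
                        if t == 0:
                            wsel = np.where(info["homes"][0] == s_id, weights, 0.0)
                        else:
                            wsel = weights * m_t[homes_prev, s_id]
                        tot = wsel.sum()
                        probs = wsel / tot if tot > 0 else weights
                        for c in rng.choice(len(weights), size=n_s, p=probs):
                            st = CD8_SUBTYPES[s_id]
                            states.append(st)
                            cell_types.append("CD8_T")
                            subclusters.append(st)
                            clone_of_cell.append(int(c))
                elif ct == "non_classical_monocyte":
                    frac_act = 0.0
                    if group != "NLS_PEM" and tp != "PRE":
                        frac_act = min(
                            1.0,
                            config.activated_fraction_base
                            + config.activated_fraction_slope * activity,
                        )
                    n_act = int(round(frac_act * k))
                    for j in range(k):
                        if j < n_act:
                            states.append("NCM_activated")
                            subclusters.append("NCM_activated")
                        else:
                            states.append("non_classical_monocyte")
                            subclusters.append("NCM_base")
                        cell_types.append("non_classical_monocyte")
                        clone_of_cell.append(-1)
                else:
                    states.extend([ct] * k)
                    cell_types.extend([ct] * k)
                    subclusters.extend([ct] * k)
                    clone_of_cell.extend([-1] * k)

            m = len(states)
            prof = np.stack([profiles[s] for s in states], axis=1)  # genes x cells
            libs = rng.lognormal(
                np.log(config.mean_library_size), config.library_size_sigma, m
            )
            mu = prof * libs[None, :]
            counts = _nb_counts(rng, mu, config.nb_dispersion).astype(np.int32)
            blocks.append(sp.csr_matrix(counts))

            barcodes = [f"{patient}_{tp}_{j:05d}" for j in range(m)]
            coords = np.array([centers[s] for s in states])
            coords = coords + rng.normal(0.0, 0.6, coords.shape)
            meta_rows.append(
                pd.DataFrame(
                    {
                        "barcode": barcodes,
                        "patient": patient,
                        "arm": prow["arm"],
                        "survival_group": group,
                        "timepoint": tp,
                        "cell_type": cell_types,
                        "subcluster": subclusters,
                        "embed_x": coords[:, 0],
                        "embed_y": coords[:, 1],
                    }
                )
            )
            is_cd8 = np.array(clone_of_cell) >= 0
            if is_cd8.any():
                cd8_barcodes = [b for b, f in zip(barcodes, is_cd8) if f]
                cdr3 = [info["cdr3"][c] for c in clone_of_cell if c >= 0]
                clono_rows.append(
                    pd.DataFrame(
                        {
                            "barcode": cd8_barcodes,
                            "chain": "TRB",
                            "cdr3_aa": cdr3,
                            "patient": patient,
                            "timepoint": tp,
                        }
                    )
                )
            # CD4 cells carry an uncoupled, stable repertoire
            is_cd4 = np.array(cell_types) == "CD4_T"
            if is_cd4.any():
                k4 = int(is_cd4.sum())
                w4 = info["w_cd4"]
                c4 = rng.choice(len(w4), size=k4, p=w4)
                clono_rows.append(
                    pd.DataFrame(
                        {
                            "barcode": [b for b, f in zip(barcodes, is_cd4) if f],
                            "chain": "TRB",
                            "cdr3_aa": [info["cdr3_cd4"][c] for c in c4],
                            "patient": patient,
                            "timepoint": tp,
                        }
                    )
                )

    counts = sp.hstack(blocks, format="csr")
    cell_meta = pd.concat(meta_rows, ignore_index=True)
    clonotypes = pd.concat(clono_rows, ignore_index=True)

    # survival: exponential hazard scaled by latent activity toward hr_true
    log_hr = np.log(config.survival_hr_true)
    hazard = config.baseline_hazard_per_month * np.exp(
        log_hr * patients["activity"].to_numpy()
    )
    os_raw = rng.exponential(1.0 / hazard)
    event = os_raw <= config.censor_horizon_months
    os_months = np.minimum(os_raw, config.censor_horizon_months)
    age = np.round(rng.uniform(45.0, 75.0, len(patients)), 1)
    survival = pd.DataFrame(
        {
            "patient": patients["patient"],
            "os_months": np.round(os_months, 3),
            "event": event,
            "age": age,
            "arm": patients["arm"],
        }
    )
    return CohortDataset(
        counts=counts,
        gene_ids=gene_ids,
        cell_meta=cell_meta,
        clonotypes=clonotypes,
        survival=survival,
    )


def _blob_centers() -> dict[str, np.ndarray]:
    """Fixed 2-D display coordinates: cell types on a circle, CD8 subtypes on
    a sub-circle around the CD8 lobe, activated monocytes offset from resting."""
    centers: dict[str, np.ndarray] = {}
    types = list(CELL_TYPES)
    for i, ct in enumerate(types):
        angle = 2 * np.pi * i / len(types)
        centers[ct] = np.array([10 * np.cos(angle), 10 * np.sin(angle)])
    cd8 = centers["CD8_T"]
    for j, st in enumerate(CD8_SUBTYPES):
        angle = 2 * np.pi * j / len(CD8_SUBTYPES)
        centers[st] = cd8 + np.array([4 * np.cos(angle), 4 * np.sin(angle)])
    centers["NCM_activated"] = centers["non_classical_monocyte"] + np.array([3.0, 3.0])
    return centers
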