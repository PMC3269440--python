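"""Generative model for expression experiments with nested batch structure.

The simulator composes, per probe g and array/sample j,

    y_gj = baseline_g + effect_g(group(j))
           + sum_levels b[unit(j,l), g] * v_l(g) * w(g, j)
           + eps_gj

with the random batch effects b drawn Normal(0, sd_l^2) independently per
(unit, probe), residual eps ~ Normal(0, residual_sd^2), a GC-vulnerability
multiplier v_l(g) that inflates the batch SD of low-GC probes at configured
levels, and an expression-coupling weight

    w(g, j) = (1 - kappa) + kappa * s(g, j)

where s is the within-sample rank of the probe's true (noise-free) expression
mapped to [0, 1].  With kappa = 0 and v = 1 this is exactly the balanced
nested Gaussian model assumed by the variance module.

Control samples ride the same batch machinery: a generic control (UHRR-like)
carries a fixed expression profile drawn independently of the biological
samples, while a pooled control carries the arithmetic mean (log2 scale) of
its member samples' true profiles.  Technical duplicates share one source
profile but receive their own batch and residual draws in two distinct batch
units.

Everything drawn is recorded in :class:`SimulationTruth` so estimators can be
checked against the realized effects, not just the nominal parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .datamodel import (
    BATCH_LEVELS,
    DataError,
    ExpressionMatrix,
    ProbeSheet,
    SampleSheet,
    gc_fraction,
)


@dataclass(frozen=True)
class GroupSpec:
    """One biological group: its non-duplicated array count and planted effects.

    ``frac_differential`` of probes receive a log2 effect drawn
    Normal(0, effect_sd^2) relative to the first (reference) group, whose
    effects are identically zero.
    """

    name: str
    n_samples: int
    frac_differential: float = 0.0
    effect_sd: float = 0.0


@dataclass(frozen=True)
class GCModel:
    """Step-function vulnerability: batch SDs of probes with GC < cutoff are
    multiplied by ``multiplier`` at the given levels (all random levels when
    ``levels`` is None)."""

    multiplier: float = 1.0
    cutoff: float = 0.55
    levels: tuple[str, ...] | None = None


@dataclass(frozen=True)
class DetectionModel:
    """Logistic map from true log2 expression to detection confidence.

    conf = sigmoid(slope * (true + Normal(0, noise_sd^2) - midpoint)).
    """

    midpoint: float = 5.5
    slope: float = 1.5
    noise_sd: float = 0.5


@dataclass(frozen=True)
class DesignSpec:
    """Full generative design.  One sample per array; the array is the
    residual-bearing unit.  ``nesting`` is ordered outermost-first and its
    counts are children-per-parent, ending in arrays-per-chip.  The total
    number of arrays must equal the samples implied by ``groups``,
    ``duplicate_plan`` (2 arrays per source), and the control counts."""

    n_probes: int = 1000
    nesting: tuple[tuple[str, int], ...] = (
        ("experiment", 3),
        ("run", 2),
        ("chip", 2),
        ("array_position", 2),
    )
    level_sd: Mapping[str, float] = field(
        default_factory=lambda: {"experiment": 0.30, "run": 0.15, "chip": 0.10}
    )
    residual_sd: float = 0.20
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    groups: tuple[GroupSpec, ...] = ()
    duplicate_plan: int = 0
    duplicate_level: str = "run"
    n_generic_controls: int = 0
    n_pooled_controls: int = 0
    gc_model: GCModel = GCModel()
    expression_coupling: float = 0.0  # kappa
    detection_model: DetectionModel = DetectionModel()
    probe_length: int = 50
    gc_beta: tuple[float, float] = (5.5, 4.5)
    outlier_chip_sd_multiplier: float = 1.0
    seed: int = 0
    biology_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise DataError("n_probes must be positive")
        names = [n for n, _ in self.nesting]
        if names != list(BATCH_LEVELS):
            raise DataError(f"nesting levels must be {BATCH_LEVELS}, got {names}")
        if any(c < 1 for _, c in self.nesting):
            raise DataError("children counts must be >= 1")
        if any(sd < 0 for sd in self.level_sd.values()) or self.residual_sd < 0:
            raise DataError("SDs must be nonnegative")
        unknown = set(self.level_sd) - set(names[:-1])
        if unknown:
            raise DataError(f"level_sd refers to unknown levels: {sorted(unknown)}")
        if not 0.0 <= self.expression_coupling <= 1.0:
            raise DataError("expression_coupling (kappa) must lie in [0, 1]")
        for g in self.groups:
            if not 0.0 <= g.frac_differential <= 1.0:
                raise DataError("frac_differential must lie in [0, 1]")

    @property
    def random_levels(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.nesting[:-1])

    @property
    def n_arrays(self) -> int:
        return int(np.prod([c for _, c in self.nesting]))

    @property
    def n_samples_required(self) -> int:
        return (
            sum(g.n_samples for g in self.groups)
            + 2 * self.duplicate_plan
            + self.n_generic_controls
            + self.n_pooled_controls
        )

    def replace(self, **kw) -> "DesignSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class SimulationTruth:
    """Everything the generator drew, keyed exactly as used in composition."""

    baselines: pd.Series  # per probe
    group_effects: pd.DataFrame  # probes x groups (reference group all zero)
    differential: pd.DataFrame  # boolean probes x groups
    true_profiles: pd.DataFrame  # probes x samples (noise-free expression)
    random_effects: dict[str, pd.DataFrame]  # level -> units x probes
    batch_shift: pd.DataFrame  # probes x samples, the summed realized shift
    gc: pd.Series  # per-probe gc_fraction
    spec: DesignSpec


def _level_units(nesting: Sequence[tuple[str, int]]) -> pd.DataFrame:
    """Array table with fully qualified unit labels, one row per array."""
    rows = []

    def expand(prefix: list[str], depth: int) -> None:
        name, count = nesting[depth]
        for i in range(1, count + 1):
            label = f"{prefix[-1]}.{name[0].upper()}{i}" if prefix else f"{name[0].upper()}{i}"
            if depth == len(nesting) - 1:
                rows.append(prefix + [label])
            else:
                expand(prefix + [label], depth + 1)

    expand([], 0)
    return pd.DataFrame(rows, columns=[n for n, _ in nesting])


def _allocate_samples(spec: DesignSpec) -> pd.DataFrame:
    """Deterministically place controls, duplicates, and group samples."""
    arrays = _level_units(spec.nesting)
    n = len(arrays)
    if spec.n_samples_required != n:
        raise DataError(
            f"design requires {spec.n_samples_required} samples but the nesting "
            f"provides {n} arrays; adjust group sizes/controls/duplicates"
        )
    arrays = arrays.copy()
    arrays["sample_id"] = ""
    arrays["role"] = ""
    arrays["group"] = pd.NA
    arrays["duplicate_id"] = pd.NA
    free = list(arrays.index)

    def take_from(unit_col: str, unit_label: str) -> int:
        for idx in free:
            if arrays.loc[idx, unit_col] == unit_label:
                free.remove(idx)
                return idx
        raise DataError(f"no free array left in {unit_col} {unit_label}")

    chips = arrays["chip"].drop_duplicates().tolist()
    group_names_ctrl = [g.name for g in spec.groups]
    # generic controls: spread across chips (UHRR-style, one per chip first);
    # duplicate_id marks the replicate set a control belongs to
    for k in range(spec.n_generic_controls):
        idx = take_from("chip", chips[k % len(chips)])
        arrays.loc[idx, ["sample_id", "role"]] = (f"G{k + 1:02d}", "generic_control")
        arrays.loc[idx, "duplicate_id"] = "UHRR"
    # pooled controls likewise; pool k cycles over the biological groups
    for k in range(spec.n_pooled_controls):
        idx = take_from("chip", chips[k % len(chips)])
        arrays.loc[idx, ["sample_id", "role"]] = (f"P{k + 1:02d}", "pooled_control")
        if group_names_ctrl:
            grp = group_names_ctrl[k % len(group_names_ctrl)]
            arrays.loc[idx, "duplicate_id"] = f"pool-{grp}"
        else:
            arrays.loc[idx, "duplicate_id"] = "pool"
    # duplicates: each source occupies two distinct units of duplicate_level
    units = arrays[spec.duplicate_level].drop_duplicates().tolist()
    if spec.duplicate_plan > 0 and len(units) < 2:
        raise DataError(
            f"duplicate_plan needs >= 2 units at level {spec.duplicate_level!r}"
        )
    group_names = [g.name for g in spec.groups] or [None]
    for k in range(spec.duplicate_plan):
        u_a = units[(2 * k) % len(units)]
        u_b = units[(2 * k + 1) % len(units)]
        if u_a == u_b:
            u_b = units[(2 * k + 2) % len(units)]
        src = f"T{k + 1:02d}"
        grp = group_names[k % len(group_names)]
        for suffix, unit in (("a", u_a), ("b", u_b)):
            try:
                idx = take_from(spec.duplicate_level, unit)
            except DataError as exc:
                raise DataError(
                    f"duplicate_plan exceeds available arrays in {unit}: {exc}"
                ) from exc
            arrays.loc[idx, "sample_id"] = src + suffix
            arrays.loc[idx, "role"] = "biological"
            arrays.loc[idx, "group"] = grp
            arrays.loc[idx, "duplicate_id"] = src
    # remaining slots: plain biological samples, groups interleaved across
    # consecutive arrays so each batch is blocked (no group confounding)
    remaining = {g.name: g.n_samples for g in spec.groups}
    order = [g.name for g in spec.groups]
    counter, gi = 1, 0
    while any(remaining.values()):
        while remaining[order[gi % len(order)]] == 0:
            gi += 1
        name = order[gi % len(order)]
        idx = free.pop(0)
        arrays.loc[idx, "sample_id"] = f"S{counter:02d}"
        arrays.loc[idx, "role"] = "biological"
        arrays.loc[idx, "group"] = name
        remaining[name] -= 1
        counter += 1
        gi += 1
    return arrays


def _make_probes(spec: DesignSpec, rng: np.random.Generator) -> ProbeSheet:
    a, b = spec.gc_beta
    gc_target = rng.beta(a, b, spec.n_probes)
    bases_gc = np.array(list("GC"))
    bases_at = np.array(list("AT"))
    seqs = []
    for t in gc_target:
        is_gc = rng.random(spec.probe_length) < t
        picks = rng.integers(0, 2, spec.probe_length)
        seq = np.where(is_gc, bases_gc[picks], bases_at[picks])
        seqs.append("".join(seq))
    frame = pd.DataFrame(
        {
            "probe_id": [f"p{i + 1:05d}" for i in range(spec.n_probes)],
            "sequence": seqs,
            "gene_id": [f"g{i + 1:05d}" for i in range(spec.n_probes)],
            "strand": rng.choice(["+", "-"], spec.n_probes),
            "probe_position_fraction": rng.random(spec.n_probes),
            "n_transcripts": 1 + rng.poisson(1.0, spec.n_probes),
            "n_exons": 1 + rng.poisson(8.0, spec.n_probes),
        }
    )
    frame["gc_fraction"] = [gc_fraction(s) for s in seqs]
    return ProbeSheet(frame)


def _rank_map(profile: np.ndarray) -> np.ndarray:
    """Within-sample rank of each probe's true expression, mapped to [0, 1]."""
    order = np.argsort(np.argsort(profile, kind="stable"), kind="stable")
    if len(profile) == 1:
        return np.full(1, 0.5)
    return order / (len(profile) - 1)


def make_pooled_control(
    truth_profiles: pd.DataFrame, member_samples: Sequence[str]
) -> pd.Series:
    """Arithmetic mean (log2 scale) of the members' true profiles."""
    members = list(member_samples)
    if not members:
        raise DataError("pooled control needs at least one member sample")
    missing = [m for m in members if m not in truth_profiles.columns]
    if missing:
        raise DataError(f"pool members absent from truth: {missing}")
    return truth_profiles[members].mean(axis=1)


def simulate_experiment(
    spec: DesignSpec,
) -> tuple[ExpressionMatrix, SampleSheet, ProbeSheet, SimulationTruth]:
    """Draw one full experiment; bit-identical for identical spec (incl. seed)."""
    bio_seed = spec.seed if spec.biology_seed is None else spec.biology_seed
    rng_bio = np.random.default_rng([101, int(bio_seed)])
    rng_noise = np.random.default_rng([202, int(spec.seed)])

    probes = _make_probes(spec, rng_bio)
    gc = probes.gc().to_numpy()
    G = spec.n_probes

    alloc = _allocate_samples(spec)
    sample_ids = alloc["sample_id"].tolist()

    baselines = rng_bio.normal(spec.baseline_mean, spec.baseline_sd, G)
    group_names = [g.name for g in spec.groups]
    effects = pd.DataFrame(0.0, index=probes.probe_ids, columns=group_names)
    differential = pd.DataFrame(False, index=probes.probe_ids, columns=group_names)
    for gi, g in enumerate(spec.groups):
        if gi == 0:
            continue  # reference group: zero effects by construction
        n_diff = int(round(g.frac_differential * G))
        idx = rng_bio.choice(G, size=n_diff, replace=False)
        eff = np.zeros(G)
        eff[idx] = rng_bio.normal(0.0, g.effect_sd, n_diff)
        effects[g.name] = eff
        differential[g.name] = np.isin(np.arange(G), idx)

    # generic-control profile: independent of the biological samples
    generic_profile = rng_bio.normal(spec.baseline_mean, spec.baseline_sd, G)

    # true (noise-free) profiles per sample
    true_profiles = pd.DataFrame(
        index=probes.probe_ids, columns=sample_ids, dtype=float
    )
    for _, row in alloc.iterrows():
        sid, role = row["sample_id"], row["role"]
        if role == "biological":
            prof = baselines.copy()
            if pd.notna(row["group"]) and row["group"] in effects.columns:
                prof = prof + effects[row["group"]].to_numpy()
            true_profiles[sid] = prof
        elif role == "generic_control":
            true_profiles[sid] = generic_profile
    # pooled controls: mean of member profiles, pool k cycles over groups
    pooled = alloc[alloc["role"] == "pooled_control"]
    bio_rows = alloc[alloc["role"] == "biological"]
    for pid, pool_tag in zip(pooled["sample_id"], pooled["duplicate_id"]):
        tag = str(pool_tag)
        if tag.startswith("pool-"):
            grp = tag[len("pool-"):]
            members = bio_rows.loc[bio_rows["group"] == grp, "sample_id"].tolist()
        else:
            members = bio_rows["sample_id"].tolist()
        if not members:
            raise DataError(f"no member samples available for pooled control {pid}")
        true_profiles[pid] = make_pooled_control(true_profiles, members).to_numpy()

    # vulnerability multipliers per level
    gm = spec.gc_model
    vulnerable = gc < gm.cutoff
    v_levels = gm.levels if gm.levels is not None else spec.random_levels

    # realized random effects per level
    random_effects: dict[str, pd.DataFrame] = {}
    outlier_chip = None
    if spec.outlier_chip_sd_multiplier != 1.0:
        outlier_chip = alloc["chip"].drop_duplicates().iloc[-1]
    for level in spec.random_levels:
        units = alloc[level].drop_duplicates().tolist()
        sd = float(spec.level_sd.get(level, 0.0))
        draws = rng_noise.normal(0.0, sd, (len(units), G))
        if level == "chip" and outlier_chip is not None:
            i = units.index(outlier_chip)
            draws[i] *= spec.outlier_chip_sd_multiplier
        random_effects[level] = pd.DataFrame(
            draws, index=units, columns=probes.probe_ids
        )

    kappa = spec.expression_coupling
    values = np.empty((G, len(sample_ids)))
    shifts = np.empty((G, len(sample_ids)))
    eps = rng_noise.normal(0.0, spec.residual_sd, (G, len(sample_ids)))
    for j, (_, row) in enumerate(alloc.iterrows()):
        prof = true_profiles[row["sample_id"]].to_numpy()
        w = (1.0 - kappa) + kappa * _rank_map(prof)
        shift = np.zeros(G)
        for level in spec.random_levels:
            b = random_effects[level].loc[row[level]].to_numpy()
            v = np.where(vulnerable, gm.multiplier, 1.0) if level in v_levels else 1.0
            shift = shift + b * v * w
        shifts[:, j] = shift
        values[:, j] = prof + shift + eps[:, j]

    dm = spec.detection_model
    latent = true_profiles.to_numpy() + rng_noise.normal(
        0.0, dm.noise_sd, (G, len(sample_ids))
    )
    detection = expit(dm.slope * (latent - dm.midpoint))

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probes.probe_ids, columns=sample_ids),
        pd.DataFrame(detection, index=probes.probe_ids, columns=sample_ids),
    )
    sheet = SampleSheet(
        alloc[["sample_id", "role", "group", "duplicate_id", *BATCH_LEVELS]]
    )
    truth = SimulationTruth(
        baselines=pd.Series(baselines, index=probes.probe_ids),
        group_effects=effects,
        differential=differential,
        true_profiles=true_profiles,
        random_effects=random_effects,
        batch_shift=pd.DataFrame(
            shifts, index=probes.probe_ids, columns=sample_ids
        ),
        gc=probes.gc(),
        spec=spec,
    )
    return matrix, sheet, probes, truth


def inject_location_scale(
    m: ExpressionMatrix,
    truth: SimulationTruth,
    sheet: SampleSheet,
    batch_level: str,
    add_sd: float = 0.5,
    scale_log_sd: float = 0.2,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Inject per-(batch, probe) additive and multiplicative batch effects.

    The additive term gamma ~ Normal(0, add_sd^2) shifts each batch's mean;
    the multiplicative term delta ~ LogNormal(0, scale_log_sd^2) rescales the
    noise about the true profile:

        y' = true + gamma_{i(j),g} + delta_{i(j),g} * (y - true)

    Returns the modified matrix plus the realized gamma and delta tables
    (batches x probes).  This is the generative counterpart of the
    location/scale model the empirical-Bayes correction assumes.
    """
    rng = np.random.default_rng([303, int(seed)])
    df = sheet.aligned_to(m.sample_ids)
    batches = df[batch_level].drop_duplicates().tolist()
    G = m.shape[0]
    gamma = pd.DataFrame(
        rng.normal(0.0, add_sd, (len(batches), G)),
        index=batches, columns=m.probe_ids,
    )
    delta = pd.DataFrame(
        np.exp(rng.normal(0.0, scale_log_sd, (len(batches), G))),
        index=batches, columns=m.probe_ids,
    )
    true = truth.true_profiles[m.sample_ids].loc[m.probe_ids].to_numpy()
    y = m.values.to_numpy()
    out = np.empty_like(y)
    for j, b in enumerate(df[batch_level]):
        g = gamma.loc[b].to_numpy()
        d = delta.loc[b].to_numpy()
        out[:, j] = true[:, j] + g + d * (y[:, j] - true[:, j])
    mat = ExpressionMatrix(
        pd.DataFrame(out, index=m.probe_ids, columns=m.sample_ids),
        m.detection.copy() if m.detection is not None else None,
    )
    return mat, gamma, delta


# ---------------------------------------------------------------------------
# canonical designs
# ---------------------------------------------------------------------------

def replicate_control_design(
    n_probes: int = 1000,
    nesting: tuple[tuple[str, int], ...] = (
        ("experiment", 3),
        ("run", 2),
        ("chip", 2),
        ("array_position", 2),
    ),
    level_sd: Mapping[str, float] | None = None,
    residual_sd: float = 0.20,
    seed: int = 0,
    **kw,
) -> DesignSpec:
    """All arrays carry replicates of one RNA source (UHRR-style design):
    a single group with zero planted effects fills every array."""
    n_arrays = int(np.prod([c for _, c in nesting]))
    return DesignSpec(
        n_probes=n_probes,
        nesting=nesting,
        level_sd=dict(level_sd or {"experiment": 0.30, "run": 0.15, "chip": 0.10}),
        residual_sd=residual_sd,
        groups=(GroupSpec("replicate", n_arrays),),
        seed=seed,
        **kw,
    )


def tumour_duplicate_design(
    n_probes: int = 2000,
    kappa: float = 0.5,
    seed: int = 0,
    level_sd: Mapping[str, float] | None = None,
    residual_sd: float = 0.20,
    gc_model: GCModel = GCModel(),
) -> DesignSpec:
    """Paired-biopsy design with duplicates and both calibrator types.

    One experiment of two runs, two chips per run, twelve arrays per chip
    (48 arrays): 14 duplicated sources split across the two runs (28 arrays),
    6 generic controls, 8 pooled controls (pre/post pools cycling over chips),
    and 6 non-duplicated samples (3 pre, 3 post).
    """
    return DesignSpec(
        n_probes=n_probes,
        nesting=(
            ("experiment", 1),
            ("run", 2),
            ("chip", 2),
            ("array_position", 12),
        ),
        level_sd=dict(level_sd or {"experiment": 0.0, "run": 0.25, "chip": 0.15}),
        residual_sd=residual_sd,
        groups=(
            GroupSpec("pre", 3, 0.0, 0.0),
            GroupSpec("post", 3, 0.10, 0.8),
        ),
        duplicate_plan=14,
        duplicate_level="run",
        n_generic_controls=6,
        n_pooled_controls=8,
        gc_model=gc_model,
        expression_coupling=kappa,
        seed=seed,
    )
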