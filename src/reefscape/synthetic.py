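"""Seeded synthetic reef studies with known ground truth.

Emulates the field design the package analyses: 3 sites x 5 habitat zones
(slope, crest, outer-, mid-, inner-flat) x 2 reconstructions, each sampled by
five 5 m cross-section transects, with per-habitat archetypes controlling the
underlying ramp, roughness, benthic cover mix and refuge rates. Complexity
peaks on the slope and crest while grazing surface area (turf cover) peaks on
the outer-flat, reproducing the canonical zonation gradient. Fish surveys are
generated with a log-linear dependence of total abundance on grazing surface
area (negative binomial with known slope), so the full inference pipeline can
be validated against the generating parameters. Tides are a two-constituent
semidiurnal harmonic with spring-neap modulation.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import BENTHIC_LABELS, BenthicSegmentation, ElevationProfile, compute_all_metrics
from .tides import TideExtremes

HABITATS = ["slope", "crest", "outer_flat", "mid_flat", "inner_flat"]

M2_PERIOD_H = 12.4206  # principal lunar semidiurnal constituent
S2_PERIOD_H = 12.0     # principal solar semidiurnal constituent


@dataclass(frozen=True)
class HabitatArchetype:
    """Generative parameters of one habitat zone."""

    name: str
    base_gradient: float          # dimensionless slope of the underlying ramp
    roughness_amplitude: float    # m, scale of midpoint-displacement noise
    cover_probs: dict             # benthic label -> probability (sums to 1)
    crevice_rate: float           # expected plantable crevices per 5 m
    overhang_rate: float          # expected plantable overhangs per 5 m

    def __post_init__(self):
        if self.roughness_amplitude < 0:
            raise ValueError("roughness_amplitude must be >= 0")
        if self.crevice_rate < 0 or self.overhang_rate < 0:
            raise ValueError("refuge rates must be >= 0")
        probs = np.array(list(self.cover_probs.values()), dtype=float)
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("cover probabilities must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("cover probabilities must sum to 1")
        unknown = set(self.cover_probs) - set(BENTHIC_LABELS)
        if unknown:
            raise ValueError(f"unknown benthic labels: {sorted(unknown)}")


# Calibration knobs, not field values: chosen so the canonical gradient
# (complexity highest slope/crest, grazing surface maximal on the outer-flat,
# mid-flat macroalgae-dominated, inner-flat sandy) is reproduced with a
# comfortable margin over patch-sampling noise at the default design size.
DEFAULT_ARCHETYPES = {
    "slope": HabitatArchetype(
        "slope", 0.55, 0.22,
        {"hard_coral": 0.28, "turf_EAM": 0.45, "macroalgae": 0.05, "sand": 0.10, "other": 0.12},
        crevice_rate=3.0, overhang_rate=2.0),
    "crest": HabitatArchetype(
        "crest", 0.12, 0.25,
        {"hard_coral": 0.36, "turf_EAM": 0.42, "macroalgae": 0.04, "sand": 0.06, "other": 0.12},
        crevice_rate=3.5, overhang_rate=2.0),
    "outer_flat": HabitatArchetype(
        "outer_flat", 0.03, 0.10,
        {"hard_coral": 0.10, "turf_EAM": 0.60, "macroalgae": 0.05, "sand": 0.13, "other": 0.12},
        crevice_rate=1.0, overhang_rate=0.5),
    "mid_flat": HabitatArchetype(
        "mid_flat", 0.02, 0.06,
        {"hard_coral": 0.05, "turf_EAM": 0.25, "macroalgae": 0.42, "sand": 0.16, "other": 0.12},
        crevice_rate=0.5, overhang_rate=0.2),
    "inner_flat": HabitatArchetype(
        "inner_flat", 0.01, 0.035,
        {"hard_coral": 0.04, "turf_EAM": 0.20, "macroalgae": 0.10, "sand": 0.54, "other": 0.12},
        crevice_rate=0.3, overhang_rate=0.1),
}

# benthos elevation relative to the tide datum (m); site-level jitter is added
DEFAULT_BENTHOS = {"slope": -2.0, "crest": 0.0, "outer_flat": 0.15, "mid_flat": 0.35, "inner_flat": 0.60}

# relative species mix and total-length class distributions (cm) for the
# roving-herbivore assemblage: parrotfish-dominated, as typical inshore
DEFAULT_SPECIES_PROFILE = {
    "Scarus_rivulatus": {"mix": 0.45, "size_probs": {(5.0, 7.5): 0.08, (7.5, 10.0): 0.12, (10.0, 15.0): 0.35, (15.0, 20.0): 0.30, (20.0, 25.0): 0.15}},
    "Siganus_doliatus": {"mix": 0.18, "size_probs": {(5.0, 7.5): 0.05, (7.5, 10.0): 0.10, (10.0, 15.0): 0.40, (15.0, 20.0): 0.35, (20.0, 25.0): 0.10}},
    "Chlorurus_microrhinos": {"mix": 0.12, "size_probs": {(10.0, 15.0): 0.10, (15.0, 20.0): 0.20, (20.0, 25.0): 0.30, (25.0, 30.0): 0.25, (30.0, 35.0): 0.15}},
    "Acanthurus_grammoptilus": {"mix": 0.10, "size_probs": {(5.0, 7.5): 0.10, (7.5, 10.0): 0.15, (10.0, 15.0): 0.45, (15.0, 20.0): 0.30}},
    "Scarus_ghobban": {"mix": 0.08, "size_probs": {(7.5, 10.0): 0.10, (10.0, 15.0): 0.35, (15.0, 20.0): 0.35, (20.0, 25.0): 0.20}},
    "Siganus_lineatus": {"mix": 0.07, "size_probs": {(10.0, 15.0): 0.30, (15.0, 20.0): 0.40, (20.0, 25.0): 0.30}},
}

DEFAULT_LW_PARAMS = pd.DataFrame(
    [
        ("Scarus_rivulatus", 0.0136, 3.04),
        ("Siganus_doliatus", 0.0182, 2.96),
        ("Chlorurus_microrhinos", 0.0150, 3.06),
        ("Acanthurus_grammoptilus", 0.0257, 2.92),
        ("Scarus_ghobban", 0.0129, 3.05),
        ("Siganus_lineatus", 0.0196, 2.98),
    ],
    columns=["species", "a", "b"],
)

DEFAULT_FISH_PARAMS = {"beta0": 2.5, "beta1": 3.0, "dispersion_k": 5.0}


# ---------------------------------------------------------------------------
# elevation profiles


def generate_profile(
    archetype: HabitatArchetype,
    length: float = 5.0,
    resolution: float = 0.005,
    seed: int = 0,
) -> ElevationProfile:
    """A seeded cross-section: base ramp plus midpoint-displacement roughness.

    Displacement amplitude halves at each subdivision level (a fairly smooth
    fractal), so fine-scale slopes stay moderate and near-vertical surfaces
    arise only where refuges are planted.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < resolution <= 0.01:
        raise ValueError("resolution must be in (0, 0.01] m")
    rng = np.random.default_rng(seed)
    levels = max(1, int(np.ceil(np.log2(length / resolution))))
    n_coarse = 2 ** levels + 1
    xc = np.linspace(0.0, length, n_coarse)
    zc = np.zeros(n_coarse)
    if archetype.roughness_amplitude > 0:
        step = n_coarse - 1
        amp = archetype.roughness_amplitude
        for _ in range(levels):
            half = step // 2
            idx = np.arange(half, n_coarse - 1, step)
            zc[idx] = 0.5 * (zc[idx - half] + zc[idx + half]) + amp * rng.standard_normal(idx.size)
            step = half
            amp *= 0.5
    x = np.arange(0.0, length + resolution / 2, resolution)
    x[-1] = min(x[-1], length)
    z = np.interp(x, xc, zc) + archetype.base_gradient * x
    return ElevationProfile(x=x, z=z)


def insert_crevice(profile: ElevationProfile, x: float, width: float, depth: float):
    """Carve a rectangular, taper-rimmed notch into the profile.

    Returns ``(new_profile, ground_truth_entry)`` where the entry is the
    ``(x, width, depth)`` triple as planted.
    """
    if width <= 0 or depth <= 0:
        raise ValueError("width and depth must be positive")
    if x < profile.x[0] or x + width > profile.x[-1]:
        raise ValueError("crevice extends outside the profile extent")
    taper = min(0.008, width / 8.0)
    z = profile.z.copy()
    xs = profile.x
    # level floor set below the LOWER rim edge, so the cavity under the spill
    # level is a full-depth rectangle even on sloping terrain
    floor = min(np.interp(x, xs, z), np.interp(x + width, xs, z)) - depth
    inside = (xs >= x) & (xs <= x + width)
    rel = xs[inside]
    f = np.clip(np.minimum((rel - x) / taper, (x + width - rel) / taper), 0.0, 1.0)
    z[inside] = np.minimum(z[inside], z[inside] * (1.0 - f) + floor * f)
    return ElevationProfile(x=xs, z=z), (float(x), float(width), float(depth))


def insert_overhang(profile: ElevationProfile, x: float, height: float):
    """Add a near-vertical step (the single-valued proxy for an overhang).

    The step rises by ``height`` over a run of ``height / 10`` m (inclination
    about 84 degrees, above the 80-degree detection threshold). Returns
    ``(new_profile, ground_truth_entry)``.
    """
    if height <= 0:
        raise ValueError("height must be positive")
    xs = profile.x
    res = profile.resolution
    # snap the ramp to whole sample steps so every segment stays steep and
    # the full height registers as vertical extent
    n_steps = max(1, int(np.floor(height / (10.0 * res))))
    run = n_steps * res
    if x < xs[0] or x + run > xs[-1]:
        raise ValueError("overhang outside the profile extent")
    i0 = int(np.searchsorted(xs, x))
    i1 = min(i0 + n_steps, xs.size - 1)
    z = profile.z.copy()
    ramp = np.clip((xs - xs[i0]) / (xs[i1] - xs[i0]), 0.0, 1.0)
    z += height * ramp
    return ElevationProfile(x=xs, z=z), (float(xs[i0]), float(height))


def generate_segmentation(
    profile: ElevationProfile,
    archetype: HabitatArchetype,
    mean_patch_length: float = 0.30,
    seed: int = 0,
) -> BenthicSegmentation:
    """Tile the transect with exponentially sized, independently labelled patches."""
    if mean_patch_length <= 0:
        raise ValueError("mean_patch_length must be positive")
    rng = np.random.default_rng(seed)
    labels = list(archetype.cover_probs.keys())
    probs = np.array([archetype.cover_probs[k] for k in labels])
    lo, hi = float(profile.x[0]), float(profile.x[-1])
    intervals = []
    pos = lo
    while pos < hi - 1e-9:
        ln = max(0.05, rng.exponential(mean_patch_length))
        end = min(hi, pos + ln)
        lab = labels[rng.choice(len(labels), p=probs)]
        intervals.append((pos, end, lab))
        pos = end
    return BenthicSegmentation(intervals=tuple(intervals))


# ---------------------------------------------------------------------------
# fish surveys and tides


def generate_fish_counts(
    grazing_fraction_by_unit,
    beta0: float,
    beta1: float,
    dispersion_k: float,
    species_profile: dict | None = None,
    seed: int = 0,
    unit_ids=None,
    n_replicates: int = 3,
    transect_length_mean: float = 47.25,
    transect_length_sd: float = 5.0,
) -> pd.DataFrame:
    """Timed-swim survey records with a log-linear grazing-abundance link.

    For each unit, the per-250 m^2 total abundance on each replicate day is
    negative binomial with mean ``exp(beta0 + beta1 * grazing_fraction)`` and
    dispersion ``dispersion_k``; the total is allocated to species and size
    classes by the ``species_profile`` mix, and observed counts on the two
    belt widths (1 m for < 10 cm TL, 5 m for larger fish) are Poisson thinned
    by the surveyed area.
    """
    g = np.asarray(grazing_fraction_by_unit, dtype=float)
    if np.any(g < 0) or np.any(g > 1):
        raise ValueError("grazing fractions must lie in [0, 1]")
    if dispersion_k <= 0:
        raise ValueError("dispersion_k must be positive")
    species_profile = species_profile or DEFAULT_SPECIES_PROFILE
    mix = np.array([v["mix"] for v in species_profile.values()], dtype=float)
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("species mix probabilities must sum to 1")
    if unit_ids is None:
        unit_ids = [("site1", f"unit{i}") for i in range(len(g))]
    rng = np.random.default_rng(seed)
    rows = []
    for (site, habitat), gf in zip(unit_ids, g):
        mu = float(np.exp(beta0 + beta1 * gf))
        for rep in range(1, n_replicates + 1):
            total = rng.negative_binomial(dispersion_k, dispersion_k / (dispersion_k + mu))
            length = float(max(20.0, rng.normal(transect_length_mean, transect_length_sd)))
            sp_counts = rng.multinomial(total, mix)
            for (sp, prof), n_sp in zip(species_profile.items(), sp_counts):
                if n_sp == 0:
                    continue
                classes = list(prof["size_probs"].keys())
                cprobs = np.array(list(prof["size_probs"].values()))
                cls_counts = rng.multinomial(n_sp, cprobs / cprobs.sum())
                for (lo, hi), n_cls in zip(classes, cls_counts):
                    if n_cls == 0:
                        continue
                    width = 1.0 if hi <= 10.0 else 5.0
                    expected = n_cls * (length * width / 250.0)
                    observed = int(rng.poisson(expected))
                    if observed == 0:
                        continue
                    rows.append(
                        {"site": site, "habitat": habitat, "replicate": rep, "species": sp,
                         "tl_lower_cm": lo, "tl_upper_cm": hi, "count": observed,
                         "transect_length_m": round(length, 2), "transect_width_m": width}
                    )
    return pd.DataFrame(
        rows,
        columns=["site", "habitat", "replicate", "species", "tl_lower_cm", "tl_upper_cm",
                 "count", "transect_length_m", "transect_width_m"],
    )


def generate_tides(
    n_days: int = 365,
    principal_amplitude: float = 1.2,
    secondary_amplitude: float = 0.4,
    mean_level: float = 1.8,
    seed: int = 0,
    start: str = "2017-05-01",
) -> TideExtremes:
    """Extremes of a two-constituent semidiurnal tide with spring-neap beats."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if principal_amplitude < 0 or secondary_amplitude < 0:
        raise ValueError("amplitudes must be >= 0")
    rng = np.random.default_rng(seed)
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    t_h = np.arange(0.0, n_days * 24.0, 1.0 / 60.0)  # minute grid, in hours
    h = (
        mean_level
        + principal_amplitude * np.cos(2 * np.pi * t_h / M2_PERIOD_H + phase1)
        + secondary_amplitude * np.cos(2 * np.pi * t_h / S2_PERIOD_H + phase2)
    )
    d = np.diff(h)
    sign = np.sign(d)
    sign[sign == 0] = 1
    turning = np.flatnonzero(np.diff(sign) != 0) + 1
    kinds = np.where(h[turning] > h[turning - 1], "high", "low")
    times = pd.Timestamp(start) + pd.to_timedelta(t_h[turning], unit="h")
    return TideExtremes(times=pd.DatetimeIndex(times), heights=h[turning], kinds=kinds)


# ---------------------------------------------------------------------------
# full study


@dataclass
class TransectData:
    site: str
    habitat: str
    reconstruction: int
    transect: int
    profile: ElevationProfile
    segmentation: BenthicSegmentation
    planted_crevices: list = field(default_factory=list)
    planted_overhangs: list = field(default_factory=list)


@dataclass
class StudyBundle:
    """Everything one synthetic field campaign produces."""

    transects: list
    fish_records: pd.DataFrame
    lw_params: pd.DataFrame
    tides: TideExtremes
    depths: pd.DataFrame           # site, habitat, true benthos level + measurements
    ground_truth: dict
    config: dict

    def unit_index(self) -> pd.DataFrame:
        return (
            pd.DataFrame([(t.site, t.habitat) for t in self.transects], columns=["site", "habitat"])
            .drop_duplicates()
            .sort_values(["site", "habitat"])
            .reset_index(drop=True)
        )


def _plant_positions(rng, length, n, margin=0.35, min_sep=0.45):
    """Well-separated feature positions, or fewer if the transect is crowded."""
    out = []
    for _ in range(200):
        if len(out) >= n:
            break
        cand = rng.uniform(margin, length - margin)
        if all(abs(cand - p) >= min_sep for p in out):
            out.append(float(cand))
    return sorted(out)


def generate_study(
    n_sites: int = 3,
    n_reconstructions: int = 2,
    n_transects: int = 5,
    seed: int = 0,
    transect_length: float = 5.0,
    resolution: float = 0.005,
    archetypes: dict | None = None,
    fish_params: dict | None = None,
    species_profile: dict | None = None,
    n_tide_days: int = 365,
) -> StudyBundle:
    """Generate a full synthetic campaign (profiles, covers, fish, tides, truth)."""
    if min(n_sites, n_reconstructions, n_transects) < 1:
        raise ValueError("all design counts must be >= 1")
    archetypes = archetypes or DEFAULT_ARCHETYPES
    fish_params = dict(DEFAULT_FISH_PARAMS, **(fish_params or {}))
    root = np.random.SeedSequence(seed)
    s_profiles, s_fish, s_tides, s_depth = root.spawn(4)
    rng = np.random.default_rng(s_profiles)

    transects = []
    planar_turf = {}
    for si in range(1, n_sites + 1):
        site = f"site{si}"
        for habitat in HABITATS:
            arch = archetypes[habitat]
            for rec in range(1, n_reconstructions + 1):
                for tr in range(1, n_transects + 1):
                    pseed = int(rng.integers(0, 2**31 - 1))
                    prof = generate_profile(arch, transect_length, resolution, seed=pseed)
                    crevs, overs = [], []
                    n_c = min(rng.poisson(arch.crevice_rate), 6)
                    n_o = min(rng.poisson(arch.overhang_rate), 4)
                    pos = _plant_positions(rng, transect_length, n_c + n_o)
                    rng.shuffle(pos)
                    for p in pos[:n_c]:
                        w = rng.uniform(0.12, 0.18)
                        d = rng.uniform(0.13, 0.20)
                        prof, entry = insert_crevice(prof, p - w / 2, w, d)
                        crevs.append(entry)
                    for p in pos[n_c : n_c + n_o]:
                        h = rng.uniform(0.13, 0.25)
                        prof, entry = insert_overhang(prof, p, h)
                        overs.append(entry)
                    seg = generate_segmentation(prof, arch, seed=int(rng.integers(0, 2**31 - 1)))
                    transects.append(
                        TransectData(site, habitat, rec, tr, prof, seg, crevs, overs)
                    )
                    lens = {}
                    for a, b, lab in seg.intervals:
                        lens[lab] = lens.get(lab, 0.0) + (b - a)
                    tot = sum(lens.values())
                    planar_turf.setdefault((site, habitat), []).append(
                        lens.get("turf_EAM", 0.0) / tot
                    )

    unit_ids = sorted(planar_turf.keys())
    grazing = np.array([float(np.mean(planar_turf[u])) for u in unit_ids])
    fish_records = generate_fish_counts(
        grazing,
        beta0=fish_params["beta0"],
        beta1=fish_params["beta1"],
        dispersion_k=fish_params["dispersion_k"],
        species_profile=species_profile,
        seed=int(np.random.default_rng(s_fish).integers(0, 2**31 - 1)),
        unit_ids=unit_ids,
    )

    tides = generate_tides(
        n_days=n_tide_days, seed=int(np.random.default_rng(s_tides).integers(0, 2**31 - 1))
    )

    drng = np.random.default_rng(s_depth)
    mean_tide = float(np.mean(tides.heights))
    high_times = tides.times[tides.kinds == "high"]
    depth_rows = []
    for site, habitat in unit_ids:
        benthos = DEFAULT_BENTHOS[habitat] + drng.normal(0.0, 0.05)
        for k in range(9):
            t_high = high_times[int(drng.integers(1, len(high_times) - 1))]
            t_meas = t_high + pd.Timedelta(minutes=int(drng.integers(-50, 50)))
            from .tides import tide_height

            true_depth = tide_height(tides, t_meas) - benthos
            depth_rows.append(
                {"site": site, "habitat": habitat, "replicate": k + 1,
                 "timestamp": t_meas, "measured_depth_m": round(true_depth + drng.normal(0, 0.03), 1),
                 "benthos_true_m": benthos}
            )
    depths = pd.DataFrame(depth_rows)

    ground_truth = {
        "fish_model_params": dict(fish_params),
        "true_grazing_fraction": {f"{s}|{h}": float(np.mean(planar_turf[(s, h)])) for s, h in unit_ids},
        "true_cover_probs": {h: archetypes[h].cover_probs for h in HABITATS},
        "benthos_levels": {f"{r['site']}|{r['habitat']}": r["benthos_true_m"] for r in depth_rows},
        "mean_tide_level": mean_tide,
        "planted_refuges": {
            f"{t.site}|{t.habitat}|{t.reconstruction}|{t.transect}": {
                "crevices": t.planted_crevices,
                "overhangs": t.planted_overhangs,
            }
            for t in transects
        },
    }
    config = {
        "seed": seed,
        "n_sites": n_sites,
        "n_reconstructions": n_reconstructions,
        "n_transects": n_transects,
        "transect_length": transect_length,
        "resolution": resolution,
        "fish_params": dict(fish_params),
        "n_tide_days": n_tide_days,
    }
    return StudyBundle(
        transects=transects,
        fish_records=fish_records,
        lw_params=DEFAULT_LW_PARAMS.copy(),
        tides=tides,
        depths=depths,
        ground_truth=ground_truth,
        config=config,
    )


def metrics_table(bundle: StudyBundle, viewshed_params=None) -> pd.DataFrame:
    """Per-transect table of the six metrics with design identifiers."""
    rows = []
    for t in bundle.transects:
        m = compute_all_metrics(t.profile, t.segmentation, viewshed_params)
        rows.append(
            {"site": t.site, "habitat": t.habitat, "reconstruction": t.reconstruction,
             "transect": t.transect, **m.as_dict()}
        )
    return pd.DataFrame(rows)


def unit_covariates(metric_df: pd.DataFrame, bundle: StudyBundle | None = None) -> pd.DataFrame:
    """Site x habitat means of the metrics, plus water depth when a bundle is given."""
    cols = ["rugosity", "verticality", "coral_cover", "refuge_count", "fov_visible", "grazing_area"]
    out = metric_df.groupby(["site", "habitat"], as_index=False)[cols].mean()
    if bundle is not None:
        from .tides import tide_correct_depth

        dep = []
        for _, r in bundle.depths.iterrows():
            dep.append(
                {"site": r["site"], "habitat": r["habitat"],
                 "benthos": tide_correct_depth(r["measured_depth_m"], r["timestamp"], bundle.tides)}
            )
        dep = pd.DataFrame(dep).groupby(["site", "habitat"], as_index=False)["benthos"].mean()
        dep["depth"] = bundle.ground_truth["mean_tide_level"] - dep["benthos"]
        out = out.merge(dep[["site", "habitat", "depth"]], on=["site", "habitat"])
    return out


def write_bundle(bundle: StudyBundle, outdir) -> None:
    """Write the standard CSV/JSON/YAML bundle (deterministic for a seed)."""
    import yaml

    out = Path(outdir)
    (out / "profiles").mkdir(parents=True, exist_ok=True)
    (out / "segments").mkdir(parents=True, exist_ok=True)
    for t in bundle.transects:
        stem = f"{t.site}_{t.habitat}_{t.reconstruction}_{t.transect}"
        pd.DataFrame({"x_m": t.profile.x, "z_m": t.profile.z}).to_csv(
            out / "profiles" / f"{stem}.csv", index=False
        )
        pd.DataFrame(t.segmentation.intervals, columns=["start_m", "end_m", "label"]).to_csv(
            out / "segments" / f"{stem}.csv", index=False
        )
    bundle.fish_records.to_csv(out / "fish_surveys.csv", index=False)
    bundle.lw_params.to_csv(out / "lw_params.csv", index=False)
    tf = bundle.tides.to_frame()
    tf["timestamp"] = tf["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    tf.to_csv(out / "tides.csv", index=False)
    dep = bundle.depths.copy()
    dep["timestamp"] = pd.to_datetime(dep["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    dep.to_csv(out / "depths.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(bundle.ground_truth, fh, indent=1, sort_keys=True, default=float)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(bundle.config, fh, sort_keys=True)
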