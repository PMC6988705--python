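"""Seeded synthetic cohorts with the statistical structure the analyses assume.

Three generators emulate the three study designs:

* a human family cohort (deletion / duplication / familial-control
  subjects in families) whose 3D facial landmark configurations carry
  planted, reciprocal genotype effects expressed as fractions of feature
  means, plus covariate-linked size trends, family-level correlation and
  per-landmark measurement noise;
* a rodent cohort (deletion / duplication / wild-type animals) with a
  19-landmark dorsal skull plus mandible landmark groups;
* larval batches with per-condition mean shifts in the ceratohyal arch
  angle, optional interaction (synergy) terms, and an uninjected control
  group in every batch.

Effects are planted geometrically — landmark subsets are displaced along
the axis of the target inter-landmark distance — because downstream
effects are defined on size-normalized features; the realized normalized
effect therefore approximates the requested fraction (exact up to the
small induced shift of the geometric mean) and is verified post hoc by
the tests. Every generator returns a machine-readable truth record of all
planted parameters and derives all randomness from one seed via
``numpy.random.SeedSequence`` stream splitting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import LandmarkConfiguration, feature_name
from .schemes import LandmarkScheme, human_face_scheme, rodent_dorsal_scheme

__all__ = [
    "CohortSpec",
    "LarvaSpec",
    "HumanCohort",
    "RodentCohort",
    "generate_human_cohort",
    "generate_rodent_cohort",
    "generate_larvae",
    "default_human_spec",
    "default_rodent_spec",
    "default_larva_spec",
    "SIXTEEN_P11_GENES",
]

# the ~30 genes of the 16p11.2 BP4-BP5 interval, as screened one-by-one
SIXTEEN_P11_GENES = (
    "SPN", "QPRT", "C16orf54", "ZG16", "KIF22", "MAZ", "PRRT2", "PAGR1",
    "MVP", "CDIPT", "SEZ6L2", "ASPHD1", "KCTD13", "TMEM219", "TAOK2",
    "HIRIP3", "INO80E", "DOC2A", "C16orf92", "FAM57B", "ALDOA", "PPP4C",
    "TBX6", "YPEL3", "GDPD3", "MAPK3", "CORO1A", "BOLA2", "SLX1A", "SULT1A3",
)


# ---------------------------------------------------------------------------
# template geometries (mm)
# ---------------------------------------------------------------------------

def _mirror_x(points: dict[str, np.ndarray], pairs: dict[str, str]) -> None:
    for left, right in pairs.items():
        p = points[left].copy()
        p[0] = -p[0]
        points[right] = p


def human_template() -> dict[str, np.ndarray]:
    """A plausible bilaterally symmetric 24-landmark adult face (mm).

    Axes: x lateral (left negative), y vertical (up positive), z depth
    (anterior positive); origin near the sellion.
    """
    pts = {
        # left side (1-8)
        "1": np.array([-52.0, 38.0, -25.0]),   # frontotemporale
        "2": np.array([-41.0, 35.0, -4.0]),    # lateral brow
        "3": np.array([-33.0, 14.0, -6.0]),    # frontozygomaticus
        "4": np.array([-13.0, 33.0, 7.0]),     # medial brow
        "5": np.array([-44.0, 16.0, -10.0]),   # exocanthion
        "6": np.array([-16.0, 17.0, 1.0]),     # endocanthion
        "7": np.array([-17.0, -4.0, 12.0]),    # alare
        "8": np.array([-26.0, -24.0, 4.0]),    # cheilion
        # midline (17-24)
        "17": np.array([0.0, 40.0, 11.0]),     # glabella
        "18": np.array([0.0, 30.0, 9.0]),      # nasion
        "19": np.array([0.0, 3.0, 29.0]),      # pronasale
        "20": np.array([0.0, -6.0, 19.0]),     # subnasale
        "21": np.array([0.0, -17.0, 16.0]),    # labiale superius
        "22": np.array([0.0, -29.0, 15.0]),    # labiale inferius
        "23": np.array([0.0, -37.0, 10.0]),    # sublabiale
        "24": np.array([0.0, -49.0, 13.0]),    # pogonion
    }
    _mirror_x(pts, {str(i): str(i + 8) for i in range(1, 9)})
    return pts


def rodent_template() -> dict[str, np.ndarray]:
    """A symmetric 19-landmark rat dorsal skull (mm): frontal, nasal and
    maxillary regions. y runs rostral (nose positive)."""
    pts = {
        "1": np.array([-6.0, 22.0, 0.0]),      # nasal, lateral
        "2": np.array([-9.0, 10.0, 1.0]),      # frontal, anterior
        "3": np.array([-4.0, 18.0, 1.5]),      # nasal, medial
        "4": np.array([-11.0, 2.0, 2.0]),      # frontal, lateral
        "5": np.array([-8.0, -6.0, 2.5]),      # parietal boundary
        "6": np.array([-12.0, -2.0, 0.5]),     # squamosal
        "7": np.array([-7.0, 14.0, -1.0]),     # maxillary, anterior
        "8": np.array([-10.0, 6.0, -2.0]),     # maxillary, posterior
        "17": np.array([0.0, 25.0, 1.0]),      # nasale
        "18": np.array([0.0, 0.0, 3.0]),       # bregma
        "19": np.array([0.0, -10.0, 2.0]),     # lambda
    }
    _mirror_x(pts, {str(i): str(i + 8) for i in range(1, 9)})
    return pts


def rodent_mandible_template() -> dict[str, np.ndarray]:
    """Landmark groups for the mandible: lower incisors plus left and right
    ramus (mm)."""
    groups = {
        "incisor_1": np.array([-0.8, 24.0, -6.0]),
        "incisor_2": np.array([0.8, 24.0, -6.0]),
        "ramus_l_1": np.array([-8.0, -6.0, -7.0]),
        "ramus_l_2": np.array([-9.0, -9.0, -5.0]),
        "ramus_l_3": np.array([-7.5, -11.0, -8.0]),
    }
    for i in (1, 2, 3):
        p = groups[f"ramus_l_{i}"].copy()
        p[0] = -p[0]
        groups[f"ramus_r_{i}"] = p
    return groups


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Design of a synthetic CNV cohort.

    ``effect_map`` maps feature name -> (DEL fraction, DUP fraction): the
    planted genotype effect as a signed fraction of that feature's template
    value. Fractions must lie within +/-0.5.
    """

    n_del: int = 45
    n_dup: int = 44
    n_ctrl: int = 139
    family_size_range: tuple[int, int] = (2, 5)
    child_age_range: tuple[float, float] = (3.0, 18.0)
    parent_age_range: tuple[float, float] = (28.0, 50.0)
    effect_map: dict[str, tuple[float, float]] = field(default_factory=dict)
    sd_family_mm: float = 0.8        # family-level landmark offset SD
    sd_landmark_mm: float = 0.6      # per-landmark measurement noise SD
    sd_size: float = 0.02            # residual log-size SD between subjects
    age_size_slope: float = 0.004    # log-size growth per year of age
    sex_size_effect: float = 0.03    # male faces larger by this log-size amount
    hc_genotype_shift: float = 1.5   # cm; DEL macrocephaly / DUP microcephaly
    n_pcs: int = 2
    missing_pc_rate: float = 0.167   # fraction of subjects lacking ancestry PCs
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_del, self.n_dup, self.n_ctrl) < 0:
            raise ValueError("cohort counts must be non-negative")
        for feat, (fd, fu) in self.effect_map.items():
            if abs(fd) > 0.5 or abs(fu) > 0.5:
                raise ValueError(f"effect fraction out of range for {feat!r}")


@dataclass
class LarvaSpec:
    """Design of a synthetic larval batch.

    ``conditions`` maps condition label (gene names joined by "+", or the
    reserved control label) -> true mean shift in degrees vs control.
    ``interactions`` maps a tuple of gene names -> extra shift (degrees)
    beyond additivity planted in the corresponding combination condition.
    """

    conditions: dict[str, float] = field(default_factory=dict)
    n_per_condition: int = 60
    control_mean_deg: float = 85.0
    sd_deg: float = 6.0
    interactions: dict[tuple[str, ...], float] = field(default_factory=dict)
    reagent: str = "mRNA"
    dose_pg: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
        if self.sd_deg <= 0:
            raise ValueError("sd_deg must be positive")


@dataclass
class HumanCohort:
    configs: list[LandmarkConfiguration]
    covariates: pd.DataFrame
    pedigree: pd.DataFrame
    truth: dict
    scheme: LandmarkScheme


@dataclass
class RodentCohort:
    configs: list[LandmarkConfiguration]
    mandibles: dict[str, dict[str, np.ndarray]]   # subject -> group label -> point
    genotypes: pd.DataFrame
    truth: dict
    scheme: LandmarkScheme


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

def default_human_effects(scheme: LandmarkScheme | None = None) -> dict[str, tuple[float, float]]:
    """Default mirror effect map: 18 facial features with deletion effects
    of 1-12% of the feature mean; the duplication effect is reciprocal
    (opposite sign, 80% magnitude) for 13 of the 18 and concordant at 40%
    magnitude for the other 5 — the observed mirror proportion."""
    scheme = scheme or human_face_scheme()
    # larger frontal and maxillary spans, shorter/narrower nose under DEL
    targets = [
        ("1-9", 0.12), ("2-10", 0.06), ("2-4", 0.08), ("4-17", 0.04),
        ("3-4", 0.05), ("1-2", 0.05), ("7-8", 0.04), ("5-16", 0.03),
        ("8-21", 0.02),
        ("18-19", -0.05), ("4-12", -0.06), ("4-15", -0.04), ("7-19", -0.03),
        ("6-18", -0.02), ("6-15", -0.02), ("19-20", -0.08), ("7-20", -0.01),
        ("7-15", -0.10),
    ]
    out: dict[str, tuple[float, float]] = {}
    for i, (feat, fdel) in enumerate(targets):
        fdup = -0.8 * fdel if i % 18 < 13 else 0.4 * fdel
        out[feat] = (fdel, fdup)
    return out


def default_rodent_effects(scheme: LandmarkScheme | None = None) -> dict[str, tuple[float, float]]:
    """Default rat effect map: larger frontal spans, smaller nasal spans
    under the deletion, duplications reciprocal across the board."""
    targets = [
        ("2-17", 0.06), ("2-18", 0.08), ("2-4", 0.05), ("4-18", 0.07),
        ("2-6", 0.04), ("4-6", 0.05), ("1-17", -0.06), ("3-17", -0.08),
        ("1-3", -0.05), ("3-7", -0.04), ("7-17", -0.05), ("1-7", -0.03),
        ("8-18", 0.03), ("7-8", -0.02), ("5-18", 0.04),
    ]
    return {feat: (fdel, -0.8 * fdel) for feat, fdel in targets}


def default_human_spec(seed: int = 0) -> CohortSpec:
    return CohortSpec(effect_map=default_human_effects(), seed=seed)


def default_rodent_spec(seed: int = 0) -> CohortSpec:
    """Rat cohort design: 23 deletion, 26 duplication, 26 wild-type."""
    return CohortSpec(
        n_del=23, n_dup=26, n_ctrl=26,
        effect_map=default_rodent_effects(),
        sd_landmark_mm=0.15, sd_size=0.015, sd_family_mm=0.0,
        seed=seed,
    )


def default_larva_spec(seed: int = 0) -> LarvaSpec:
    """Single-gene overexpression screen across the 30 interval genes:
    group mean CHA shifts of up to -4 degrees, 24 of 30 negative, with
    per-larva SD of 6 degrees — the scale seen in larval batches."""
    rng = np.random.default_rng(12345)  # fixed pattern, not per-run noise
    shifts: dict[str, float] = {}
    strong = {"SEZ6L2": -4.0, "TAOK2": -3.0, "SPN": -2.5, "C16orf54": -2.5,
              "ASPHD1": -2.2, "INO80E": -2.0, "FAM57B": -2.0}
    negatives = [g for g in SIXTEEN_P11_GENES if g not in strong]
    for g in SIXTEEN_P11_GENES:
        if g in strong:
            shifts[g] = strong[g]
    neg_rest = negatives[:17]
    pos_rest = negatives[17:]
    for g in neg_rest:
        shifts[g] = float(-rng.uniform(0.2, 1.5))
    for g in pos_rest:
        shifts[g] = float(rng.uniform(0.2, 1.0))
    return LarvaSpec(conditions=shifts, seed=seed)


# ---------------------------------------------------------------------------
# effect planting
# ---------------------------------------------------------------------------

def _normalized_template_features(
    points: dict[str, np.ndarray], scheme: LandmarkScheme
) -> dict[str, float]:
    from .geometry import (average_symmetric, compute_pairwise_distances,
                           geometric_mean_normalize)
    cfg = LandmarkConfiguration("_template", {k: v for k, v in points.items()})
    merged = average_symmetric(compute_pairwise_distances(cfg, scheme), scheme)
    return geometric_mean_normalize(merged)


def _planted_displacements(
    template: dict[str, np.ndarray],
    scheme: LandmarkScheme,
    fractions: dict[str, float],
    tol: float = 1e-9,
    max_iter: int = 300,
) -> dict[str, np.ndarray]:
    """Landmark displacement field realizing the requested fractional
    changes of the *normalized* target features.

    The planted effect is defined on size-normalized features, so the
    solver works with the exact Jacobian of normalized features with
    respect to landmark coordinates — including the geometric-mean term,
    whose absence would leave a scale direction that raw-distance
    constraints chase indefinitely. Mirror-class members enter jointly so
    left and right forms shift alike and the template stays bilaterally
    symmetric. The nonlinear system is solved by Levenberg-Marquardt with
    homotopy staging (targets ramped up in quarters), which handles
    fraction magnitudes up to the permitted +/-0.5 where a plain
    Gauss-Newton step diverges. Raises if the requested combination is
    geometrically unattainable.
    """
    labels = list(scheme.labels)
    n_lab = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    classes: dict[str, list[tuple[str, str]]] = {}
    for pair in itertools.combinations(labels, 2):
        classes.setdefault(feature_name(pair, scheme), []).append(pair)
    unknown = [f for f in fractions if f not in classes]
    if unknown:
        raise KeyError(f"effect map references unknown features {unknown}")
    if not fractions:
        return {lab: np.zeros(3) for lab in labels}
    feat_names = list(classes)
    base = _normalized_template_features(template, scheme)
    target_feats = list(fractions)

    def evaluate(disp):
        """Normalized target values and their Jacobian at a displacement."""
        cur = {lab: template[lab] + disp[idx[lab]] for lab in labels}
        m, row_m = {}, {}
        for f in feat_names:
            vals, rows = [], []
            for a, b in classes[f]:
                u = cur[b] - cur[a]
                d = float(np.linalg.norm(u))
                u = u / d
                row = np.zeros(3 * n_lab)
                row[3 * idx[b]: 3 * idx[b] + 3] = u
                row[3 * idx[a]: 3 * idx[a] + 3] = -u
                vals.append(d)
                rows.append(row)
            m[f] = float(np.mean(vals))
            row_m[f] = np.mean(rows, axis=0)
        gm = float(np.exp(np.mean([np.log(m[f]) for f in feat_names])))
        gm_row = np.mean([row_m[f] / m[f] for f in feat_names], axis=0)
        vals = np.array([m[f] / gm for f in target_feats])
        J = np.vstack([(row_m[f] - m[f] * gm_row) / gm for f in target_feats])
        return vals, J

    disp = np.zeros((n_lab, 3))
    for stage in (0.25, 0.5, 0.75, 1.0):
        targets = np.array([base[f] * (1.0 + stage * fractions[f]) for f in target_feats])
        vals, J = evaluate(disp)
        resid = targets - vals
        nr = float(np.linalg.norm(resid))
        lam = 1e-2
        for _ in range(max_iter):
            if nr < tol:
                break
            JJt = J @ J.T
            scale = float(np.trace(JJt)) / len(JJt)
            delta = J.T @ np.linalg.solve(
                JJt + lam * scale * np.eye(len(JJt)), resid
            )
            cand = disp + delta.reshape(n_lab, 3)
            vals2, J2 = evaluate(cand)
            resid2 = targets - vals2
            nr2 = float(np.linalg.norm(resid2))
            if nr2 < nr:
                disp, J, resid, nr = cand, J2, resid2, nr2
                lam = max(lam / 3.0, 1e-12)
            else:
                lam *= 10.0
                if lam > 1e10:
                    break
        if stage == 1.0 and nr >= max(tol, 1e-8):
            raise RuntimeError(
                "effect map is geometrically unattainable: residual "
                f"{nr:.3e} on normalized targets; reduce or decouple the "
                "requested fractions"
            )
    return {lab: disp[idx[lab]] for lab in labels}


def _genotype_templates(template, scheme, effect_map):
    """Per-genotype displaced template copies (CTRL = the base template)."""
    out = {"CTRL": {k: v.copy() for k, v in template.items()}}
    for gi, geno in enumerate(("DEL", "DUP")):
        frac = {f: eff[gi] for f, eff in effect_map.items()}
        disp = _planted_displacements(template, scheme, frac)
        out[geno] = {k: template[k] + disp[k] for k in template}
    return out


def _random_rotation(rng) -> np.ndarray:
    # QR of a Gaussian matrix gives a Haar-uniform rotation (det fixed to +1)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# ---------------------------------------------------------------------------
# human cohort
# ---------------------------------------------------------------------------

def _assign_families(spec: CohortSpec, rng) -> pd.DataFrame:
    """Family sizes in the configured range, one carrier per family while
    they last; within a family the two oldest members act as parents."""
    n_total = spec.n_del + spec.n_dup + spec.n_ctrl
    lo, hi = spec.family_size_range
    sizes: list[int] = []
    remaining = n_total
    while remaining > 0:
        s = min(int(rng.integers(lo, hi + 1)), remaining)
        if remaining - s == 1:  # avoid a leftover singleton family
            s = min(s + 1, remaining)
        sizes.append(s)
        remaining -= s
    genotype_pool = ["DEL"] * spec.n_del + ["DUP"] * spec.n_dup
    rng.shuffle(genotype_pool)
    rows = []
    sid = 0
    for fam_idx, size in enumerate(sizes):
        fam = f"F{fam_idx:03d}"
        carriers = []
        # one carrier per family while carriers remain; extras once families run out
        if genotype_pool:
            carriers.append(genotype_pool.pop())
        members = ["CTRL"] * size
        for c in carriers[: size]:
            members[int(rng.integers(size))] = c
        for j, geno in enumerate(members):
            rows.append({"subject_id": f"S{sid:03d}", "family_id": fam,
                         "genotype": geno, "member_index": j})
            sid += 1
    df = pd.DataFrame(rows)
    # distribute any leftover carriers (more carrier groups than families)
    for geno in genotype_pool:
        ctrl_rows = df.index[df["genotype"] == "CTRL"]
        df.loc[ctrl_rows[int(rng.integers(len(ctrl_rows)))], "genotype"] = geno
    return df


def generate_human_cohort(spec: CohortSpec | None = None) -> HumanCohort:
    """Synthetic human family cohort with planted reciprocal facial effects.

    Returns landmark configurations (randomly rotated and translated, as
    acquired images would be), a covariate table (genotype, age, sex, head
    circumference, BMI, ancestry PCs with a configurable missing fraction,
    family id), a pedigree, and the truth record of every planted
    parameter. Deterministic in ``spec.seed``.
    """
    spec = spec or default_human_spec()
    scheme = human_face_scheme()
    ss = np.random.SeedSequence(spec.seed)
    rng_fam, rng_cov, rng_geom = [np.random.default_rng(s) for s in ss.spawn(3)]

    table = _assign_families(spec, rng_fam)
    template = human_template()
    geno_templates = _genotype_templates(template, scheme, spec.effect_map)

    # ages: the two lowest member indices in each family are parents
    ages = np.empty(len(table))
    is_parent = np.zeros(len(table), bool)
    for fam, idx in table.groupby("family_id").groups.items():
        idx = list(idx)
        parents = idx[:2] if len(idx) >= 3 else idx[:1]
        for i in idx:
            if i in parents:
                ages[i] = rng_cov.uniform(*spec.parent_age_range)
                is_parent[i] = True
            else:
                ages[i] = rng_cov.uniform(*spec.child_age_range)

    sex = np.where(rng_cov.random(len(table)) < 0.5, "M", "F")
    geno = table["genotype"].to_numpy()
    hc = (
        48.0 + 2.2 * np.log(ages)
        + spec.hc_genotype_shift * ((geno == "DEL").astype(float) - (geno == "DUP"))
        + rng_cov.normal(0, 1.2, len(table))
    )
    bmi = np.clip(15.0 + 0.22 * ages + rng_cov.normal(0, 2.2, len(table)), 12, 42)

    fams = table["family_id"].unique()
    fam_pc = {f: rng_cov.normal(0, 1.0, spec.n_pcs) for f in fams}
    pcs = np.vstack([
        fam_pc[f] + rng_cov.normal(0, 0.3, spec.n_pcs)
        for f in table["family_id"]
    ])
    pc_missing = rng_cov.random(len(table)) < spec.missing_pc_rate

    fam_offsets = {
        f: rng_geom.normal(0, spec.sd_family_mm, size=(len(scheme.labels), 3))
        for f in fams
    }
    label_order = list(scheme.labels)

    configs = []
    for i, row in table.iterrows():
        base = geno_templates[row["genotype"]]
        log_size = (
            spec.age_size_slope * (ages[i] - 25.0)
            + (spec.sex_size_effect if sex[i] == "M" else 0.0)
            + rng_geom.normal(0, spec.sd_size)
        )
        scale = float(np.exp(log_size))
        off = fam_offsets[row["family_id"]]
        pts = np.vstack([base[lab] for lab in label_order])
        pts = scale * (pts + off) + rng_geom.normal(0, spec.sd_landmark_mm, pts.shape)
        R = _random_rotation(rng_geom)
        t = rng_geom.normal(0, 50.0, 3)
        pts = pts @ R.T + t
        configs.append(LandmarkConfiguration(
            subject_id=row["subject_id"],
            coords={lab: pts[j] for j, lab in enumerate(label_order)},
        ))

    cov = pd.DataFrame({
        "subject_id": table["subject_id"],
        "genotype": geno,
        "age": ages,
        "sex": sex,
        "head_circumference": hc,
        "bmi": bmi,
        "family_id": table["family_id"],
    })
    for k in range(spec.n_pcs):
        col = pcs[:, k].copy()
        col[pc_missing] = np.nan
        cov[f"PC{k + 1}"] = col

    ped_rows = []
    for fam, idx in table.groupby("family_id").groups.items():
        idx = list(idx)
        parents = [table.loc[i, "subject_id"] for i in idx if is_parent[i]]
        for i in idx:
            sid = table.loc[i, "subject_id"]
            if is_parent[i] or len(parents) < 2:
                ped_rows.append({"subject_id": sid, "father_id": None, "mother_id": None})
            else:
                ped_rows.append({"subject_id": sid, "father_id": parents[0],
                                 "mother_id": parents[1]})
    pedigree = pd.DataFrame(ped_rows)

    truth = {
        "effect_map": dict(spec.effect_map),
        "seed": spec.seed,
        "n": {"DEL": spec.n_del, "DUP": spec.n_dup, "CTRL": spec.n_ctrl},
        "variance": {"sd_family_mm": spec.sd_family_mm,
                     "sd_landmark_mm": spec.sd_landmark_mm,
                     "sd_size": spec.sd_size},
        "covariate_effects": {"age_size_slope": spec.age_size_slope,
                              "sex_size_effect": spec.sex_size_effect,
                              "hc_genotype_shift": spec.hc_genotype_shift},
        "families": table.set_index("subject_id")["family_id"].to_dict(),
    }
    return HumanCohort(configs=configs, covariates=cov, pedigree=pedigree,
                       truth=truth, scheme=scheme)


# ---------------------------------------------------------------------------
# rodent cohort
# ---------------------------------------------------------------------------

def generate_rodent_cohort(spec: CohortSpec | None = None) -> RodentCohort:
    """Synthetic rodent skull cohort: dorsal landmark configurations plus
    mandible landmark groups, with planted reciprocal effects. The default
    spec matches the rat design (23 Del/+, 26 Dup/+, 26 wild-type)."""
    spec = spec or default_rodent_spec()
    scheme = rodent_dorsal_scheme()
    ss = np.random.SeedSequence(spec.seed)
    rng_asn, rng_geom = [np.random.default_rng(s) for s in ss.spawn(2)]

    genos = (["DEL"] * spec.n_del + ["DUP"] * spec.n_dup + ["CTRL"] * spec.n_ctrl)
    rng_asn.shuffle(genos)
    subjects = [f"R{i:03d}" for i in range(len(genos))]
    sex = np.where(rng_asn.random(len(genos)) < 0.5, "M", "F")

    template = rodent_template()
    geno_templates = _genotype_templates(template, scheme, spec.effect_map)
    mand_template = rodent_mandible_template()
    label_order = list(scheme.labels)

    configs, mandibles = [], {}
    for i, (sid, g) in enumerate(zip(subjects, genos)):
        scale = float(np.exp(rng_geom.normal(0, spec.sd_size)
                             + (0.01 if sex[i] == "M" else 0.0)))
        pts = np.vstack([geno_templates[g][lab] for lab in label_order])
        pts = scale * pts + rng_geom.normal(0, spec.sd_landmark_mm, pts.shape)
        R = _random_rotation(rng_geom)
        t = rng_geom.normal(0, 10.0, 3)
        configs.append(LandmarkConfiguration(
            subject_id=sid,
            coords={lab: pts[j] @ R.T + t for j, lab in enumerate(label_order)},
        ))
        # mandible: DEL shorter ML (-3%), DUP longer (+3%); same rigid motion
        ml_scale = {"DEL": 0.97, "DUP": 1.03, "CTRL": 1.0}[g]
        mand = {}
        for lab, p in mand_template.items():
            q = p.copy()
            q[1] *= ml_scale  # rostro-caudal stretch changes length, not width
            q = scale * q + rng_geom.normal(0, spec.sd_landmark_mm, 3)
            mand[lab] = q @ R.T + t
        mandibles[sid] = mand

    genotypes = pd.DataFrame({"subject_id": subjects, "genotype": genos, "sex": sex})
    truth = {
        "effect_map": dict(spec.effect_map),
        "ml_fraction": {"DEL": -0.03, "DUP": 0.03},
        "seed": spec.seed,
        "n": {"DEL": spec.n_del, "DUP": spec.n_dup, "CTRL": spec.n_ctrl},
    }
    return RodentCohort(configs=configs, mandibles=mandibles,
                        genotypes=genotypes, truth=truth, scheme=scheme)


# ---------------------------------------------------------------------------
# larvae
# ---------------------------------------------------------------------------

def generate_larvae(spec: LarvaSpec | None = None,
                    control: str = "uninjected") -> tuple[pd.DataFrame, dict]:
    """Synthetic larval batch: per-condition normal CHA draws around the
    control mean plus planted shifts (and interaction terms for
    combination conditions), always including uninjected controls."""
    spec = spec or default_larva_spec()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rows = []

    def add(cond, mean, reagent, dose):
        vals = rng.normal(mean, spec.sd_deg, spec.n_per_condition)
        for v in vals:
            rows.append({"larva_id": f"L{len(rows):04d}", "condition": cond,
                         "genes": cond if cond != control else "",
                         "reagent": reagent, "dose_pg": dose,
                         "cha_deg": float(np.clip(v, 1.0, 179.0))})

    add(control, spec.control_mean_deg, "uninjected", 0.0)
    for cond, shift in spec.conditions.items():
        genes = tuple(cond.split("+"))
        extra = 0.0
        for combo, syn in spec.interactions.items():
            if set(combo) <= set(genes) and len(combo) >= 2:
                extra += syn
        add(cond, spec.control_mean_deg + shift + extra, spec.reagent, spec.dose_pg)

    batch = pd.DataFrame(rows)
    truth = {
        "shifts": dict(spec.conditions),
        "interactions": {"+".join(k): v for k, v in spec.interactions.items()},
        "control_mean_deg": spec.control_mean_deg,
        "sd_deg": spec.sd_deg,
        "n_per_condition": spec.n_per_condition,
        "seed": spec.seed,
    }
    return batch, truth
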