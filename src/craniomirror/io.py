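"""File formats, configuration and the end-to-end pipeline driver.

Landmark coordinates are read from long-format CSV (subject_id, landmark,
x, y, z; mm) or from the TPS dialect used by morphometrics tools (LM3=k
blocks of coordinate lines followed by an ID= line). Schemes can be loaded
from YAML. Results are written as TSV; a pipeline run leaves a plain-text
run log recording the seed, package versions and row-drop accounting.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import effect_table, impute_ancestry_pcs, univariate_effect_table
from .classify import lda_fit_predict, loocv_lda, residualize
from .geometry import LandmarkConfiguration, feature_table, mandible_metrics
from .mirror import mirror_result
from .schemes import LandmarkScheme, human_face_scheme, rodent_dorsal_scheme
from .simulate import (CohortSpec, LarvaSpec, default_human_spec,
                       default_larva_spec, default_rodent_spec,
                       generate_human_cohort, generate_larvae,
                       generate_rodent_cohort)
from .zebrafish import anova_tukey, normalize_to_controls, summarize_conditions

logger = logging.getLogger(__name__)

__all__ = [
    "read_landmarks",
    "read_landmarks_csv",
    "read_landmarks_tps",
    "load_scheme",
    "write_features",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# landmark readers
# ---------------------------------------------------------------------------

def read_landmarks_csv(path, scheme: LandmarkScheme) -> list[LandmarkConfiguration]:
    """Long-format landmark CSV -> validated configurations.

    Columns: subject_id, landmark, x, y, z. Unknown landmark labels and
    malformed rows raise with the 1-based file line number.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "landmark": str})
    required = {"subject_id", "landmark", "x", "y", "z"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    known = set(scheme.labels)
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if row["landmark"] not in known:
            raise ValueError(
                f"{path}, line {line}: unknown landmark label {row['landmark']!r}"
            )
        try:
            [float(row[c]) for c in ("x", "y", "z")]
        except (TypeError, ValueError):
            raise ValueError(f"{path}, line {line}: non-numeric coordinates") from None
    configs = []
    for sid, sub in df.groupby("subject_id", sort=True):
        coords = {
            r["landmark"]: np.array([r["x"], r["y"], r["z"]], dtype=float)
            for _, r in sub.iterrows()
        }
        missing = frozenset(set(scheme.labels) - set(coords))
        configs.append(LandmarkConfiguration(subject_id=str(sid), coords=coords,
                                             missing=missing))
    logger.info("%s: %d subjects, %d landmark rows", path, len(configs), len(df))
    return configs


def read_landmarks_tps(path, scheme: LandmarkScheme) -> list[LandmarkConfiguration]:
    """TPS-dialect reader: ``LM3=k`` header, k coordinate lines, ``ID=``.

    Points are assigned to scheme labels in scheme order; a block with a
    different point count than the scheme raises with its line number.
    """
    configs = []
    labels = scheme.labels
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM3="):
            raise ValueError(f"{path}, line {i + 1}: expected LM3= block header, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError:
            raise ValueError(f"{path}, line {i + 1}: malformed LM3 count") from None
        if k != len(labels):
            raise ValueError(
                f"{path}, line {i + 1}: block has {k} points but scheme "
                f"{scheme.name!r} defines {len(labels)}"
            )
        pts = []
        for j in range(k):
            ln = lines[i + 1 + j].strip()
            parts = ln.split()
            if len(parts) != 3:
                raise ValueError(f"{path}, line {i + 2 + j}: expected 3 coordinates")
            try:
                pts.append([float(v) for v in parts])
            except ValueError:
                raise ValueError(f"{path}, line {i + 2 + j}: non-numeric coordinates") from None
        idline = lines[i + 1 + k].strip()
        if not idline.upper().startswith("ID="):
            raise ValueError(f"{path}, line {i + 2 + k}: expected ID= line")
        sid = idline.split("=", 1)[1]
        coords = {lab: np.asarray(p) for lab, p in zip(labels, pts)}
        configs.append(LandmarkConfiguration(subject_id=sid, coords=coords))
        i += k + 2
    return configs


def read_landmarks(path, scheme: LandmarkScheme, format: str | None = None):
    """Dispatch on ``format`` ('csv' | 'tps'), defaulting to the suffix."""
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "csv":
        return read_landmarks_csv(path, scheme)
    if fmt == "tps":
        return read_landmarks_tps(path, scheme)
    raise ValueError(f"unknown landmark format {fmt!r}")


def load_scheme(path) -> LandmarkScheme:
    """Scheme from a YAML config: labels+roles, pairing, angle triples,
    mandible groups."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return LandmarkScheme(
        name=cfg["name"],
        landmarks=tuple((str(l), r) for l, r in cfg["landmarks"]),
        pairing={str(k): str(v) for k, v in cfg.get("pairing", {}).items()},
        species=cfg.get("species", "human"),
        angles={k: tuple(str(x) for x in v) for k, v in cfg.get("angles", {}).items()},
        mandible_groups={k: tuple(str(x) for x in v)
                         for k, v in cfg.get("mandible_groups", {}).items()},
    )


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_BUILTIN_SCHEMES = {"human24": human_face_scheme, "rat_dorsal19": rodent_dorsal_scheme}


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return dict(config)
    with open(config) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config, outdir) -> Path:
    """Run one of the three analyses end to end from a config mapping/file.

    Config keys: ``analysis`` (human | rodent | fish), ``seed``, ``alpha``,
    and either ``synthetic: true`` (generate the cohort) or input paths
    (``landmarks``, ``covariates``, ``pedigree``, ``larvae``); supplying
    both is refused as ambiguous. Writes feature, effect, mirror,
    classification and/or condition-summary TSVs plus ``run_log.txt``.
    """
    cfg = _load_config(config)
    analysis = cfg.get("analysis")
    if analysis not in ("human", "rodent", "fish"):
        raise ValueError("config must set analysis: human | rodent | fish")
    seed = int(cfg.get("seed", 0))
    alpha = float(cfg.get("alpha", 0.05))
    synthetic = bool(cfg.get("synthetic", False))
    input_keys = [k for k in ("landmarks", "covariates", "larvae") if cfg.get(k)]
    if synthetic and input_keys:
        raise ValueError(
            f"ambiguous config: synthetic generation requested but input "
            f"paths {input_keys} also given — supply one or the other"
        )
    if not synthetic and not input_keys:
        raise ValueError("config needs either synthetic: true or input paths")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"craniomirror {__version__}",
        f"started {datetime.datetime.now().isoformat(timespec='seconds')}",
        f"analysis {analysis} seed {seed} alpha {alpha} synthetic {synthetic}",
    ]

    if analysis == "fish":
        if synthetic:
            batch, truth = generate_larvae(LarvaSpec(**cfg.get("larva_spec", {}))
                                           if cfg.get("larva_spec") else
                                           default_larva_spec(seed=seed))
            (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
        else:
            batch = pd.read_csv(cfg["larvae"], sep="\t")
        batch = normalize_to_controls(batch)
        res = anova_tukey(batch)
        summarize_conditions(batch).to_csv(outdir / "condition_summary.tsv",
                                           sep="\t", index=False)
        res.pairwise.to_csv(outdir / "tukey_pairwise.tsv", sep="\t", index=False)
        res.vs_control().to_csv(outdir / "tukey_vs_control.tsv", sep="\t", index=False)
        log_lines.append(f"anova F={res.f_stat:.4g} p={res.p_value:.4g} "
                         f"n_larvae={len(batch)}")
        (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        return outdir

    # human / rodent landmark analyses
    if analysis == "human":
        scheme = human_face_scheme()
        if synthetic:
            spec = CohortSpec(**cfg["cohort_spec"]) if cfg.get("cohort_spec") \
                else default_human_spec(seed=seed)
            coh = generate_human_cohort(spec)
            configs, covariates, pedigree = coh.configs, coh.covariates, coh.pedigree
        else:
            if cfg.get("scheme"):
                scheme = load_scheme(cfg["scheme"])
            configs = read_landmarks(cfg["landmarks"], scheme, cfg.get("format"))
            covariates = pd.read_csv(cfg["covariates"], sep="\t")
            pedigree = (pd.read_csv(cfg["pedigree"], sep="\t")
                        if cfg.get("pedigree") else None)
        feats = feature_table(configs, scheme)
        write_features(feats, outdir / "features.tsv")
        if pedigree is not None:
            n_missing = int(covariates.filter(regex="^PC").isna().any(axis=1).sum())
            covariates = impute_ancestry_pcs(covariates, pedigree, seed=seed)
            n_imp = int(covariates["pc_imputed"].isin(["sibling", "parent"]).sum())
            log_lines.append(f"ancestry PCs: {n_missing} subjects missing, "
                             f"{n_imp} imputed from relatives, "
                             f"{n_missing - n_imp} remain missing")
        eff = effect_table(feats, covariates.drop(columns=["pc_imputed"],
                                                  errors="ignore"))
        eff.to_csv(outdir / "effects.tsv", sep="\t", index=False)
        sig = eff[(eff["contrast"] == "DEL") & (eff["p_holm"] < alpha)]["feature"]
        subset = list(sig) if len(sig) >= 3 else list(feats.columns)
        dels = eff[eff["contrast"] == "DEL"].set_index("feature")["coef"]
        dups = eff[eff["contrast"] == "DUP"].set_index("feature")["coef"]
        mr = mirror_result(dels, dups, subset)
        pd.DataFrame([{
            "n_features": mr.n_features, "pearson_r": mr.pearson_r,
            "r_pvalue": mr.r_pvalue, "n_opposite": mr.n_success,
            "sign_p_one_sided": mr.sign_p_one_sided,
        }]).to_csv(outdir / "mirror.tsv", sep="\t", index=False)
        # classification on the FDR-significant distance set
        fdr_sig = eff[(eff["q_bh"] < alpha)]["feature"].unique()
        cov_idx = covariates.set_index("subject_id")
        covcols = [c for c in ("age", "head_circumference", "bmi", "sex")
                   if c in cov_idx.columns]
        covcols += [c for c in cov_idx.columns if c.startswith("PC")]
        use = [f for f in fdr_sig if f in feats.columns]
        if len(use) >= 2:
            resid = residualize(feats[use], cov_idx[covcols],
                                groups=cov_idx["family_id"])
            labels = cov_idx["genotype"].reindex(resid.index)
            cls = loocv_lda(resid, labels)
            cls.confusion.to_csv(outdir / "classification_confusion.tsv", sep="\t")
            pd.DataFrame({
                "genotype": list(cls.sensitivity),
                "sensitivity": list(cls.sensitivity.values()),
                "specificity": [cls.specificity[g] for g in cls.sensitivity],
            }).to_csv(outdir / "classification_rates.tsv", sep="\t", index=False)
            log_lines.append(f"loocv total correct rate {cls.total_correct_rate:.3f} "
                             f"on {len(use)} FDR-significant features")
        log_lines.append(f"features {feats.shape[1]} subjects {feats.shape[0]} "
                         f"mirror r {mr.pearson_r:.3f}")
    else:  # rodent
        scheme = rodent_dorsal_scheme()
        if synthetic:
            spec = CohortSpec(**cfg["cohort_spec"]) if cfg.get("cohort_spec") \
                else default_rodent_spec(seed=seed)
            coh = generate_rodent_cohort(spec)
            configs, genotypes, mandibles = coh.configs, coh.genotypes, coh.mandibles
        else:
            if cfg.get("scheme"):
                scheme = load_scheme(cfg["scheme"])
            configs = read_landmarks(cfg["landmarks"], scheme, cfg.get("format"))
            genotypes = pd.read_csv(cfg["covariates"], sep="\t")
            mandibles = None
        feats = feature_table(configs, scheme)
        if mandibles:
            ml, mw = {}, {}
            for sid, groups in mandibles.items():
                inc = [v for k, v in groups.items() if k.startswith("incisor")]
                left = [v for k, v in groups.items() if k.startswith("ramus_l")]
                right = [v for k, v in groups.items() if k.startswith("ramus_r")]
                ml[sid], mw[sid] = mandible_metrics(inc, left, right)
            feats["ML"] = pd.Series(ml)
            feats["MW"] = pd.Series(mw)
        write_features(feats, outdir / "features.tsv")
        geno = genotypes.set_index("subject_id")["genotype"]
        eff = univariate_effect_table(feats, geno)
        eff.to_csv(outdir / "effects.tsv", sep="\t", index=False)
        dels = eff[eff["contrast"] == "DEL"].set_index("feature")["coef"]
        dups = eff[eff["contrast"] == "DUP"].set_index("feature")["coef"]
        mr = mirror_result(dels, dups)   # all features, as in the rat analysis
        pd.DataFrame([{
            "n_features": mr.n_features, "pearson_r": mr.pearson_r,
            "r_pvalue": mr.r_pvalue, "n_opposite": mr.n_success,
            "sign_p_one_sided": mr.sign_p_one_sided,
        }]).to_csv(outdir / "mirror.tsv", sep="\t", index=False)
        n_fdr = int((eff["q_bh"] < alpha).sum())
        log_lines.append(f"features {feats.shape[1]} animals {feats.shape[0]} "
                         f"FDR<{alpha}: {n_fdr} mirror r {mr.pearson_r:.3f}")

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return outdir
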