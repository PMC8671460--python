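"""Synthetic screens, expression matrices and calibration sets with ground truth.

Every generator plants a known truth object next to its data so each
downstream stage (threshold calibration, activity calling, clustering and
embedding, differential sensitivity, differential expression, correlation
shortlisting, enrichment) can be scored against what was actually planted.

The screen generator emulates a single-dose pooled viability screen: each
compound/line entry is a log fold-change (logFC) versus vehicle, Gaussian
noise around a planted mean shift.  Active compounds kill through their
mechanism of action (MOA): each MOA has a latent per-line susceptibility in
[0, 1] (Bernoulli x Uniform, so some lines fully resist each MOA), and a
compound's planted shift on a line is its own potency times that latent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .screenio import DrugResponseMatrix

__all__ = [
    "SyntheticScreenTruth",
    "SyntheticExpressionTruth",
    "generate_screen",
    "generate_expression",
    "generate_calibration_set",
    "generate_differential_screen",
    "random_gene_sets",
    "write_screen",
]

# Study-condition defaults for the screen generator (fixed once; see methods note).
DEFAULT_N_COMPOUNDS = 500
DEFAULT_N_LINES = 28
DEFAULT_FRAC_ACTIVE = 0.2
DEFAULT_EFFECT_MU = -2.5
DEFAULT_NOISE_SD = 0.4
_EFFECT_SPREAD = 0.3          # per-compound potency sd around effect_mu
_LATENT_PROB = 0.6            # chance a line is at all susceptible to a MOA
_LATENT_RANGE = (0.5, 1.0)    # susceptibility magnitude when susceptible
_CATEGORY_PROPS = {"targeted cancer": 0.21, "chemotherapy": 0.02, "non-oncology": 0.77}


@dataclass
class SyntheticScreenTruth:
    """Planted ground truth behind a synthetic screen."""

    active_compounds: set[str]
    effect_size: pd.DataFrame          # compounds x lines planted mean shift (<= 0)
    moa_assignment: dict[str, str]     # compound -> MOA label
    moa_latent: pd.DataFrame           # MOA x lines susceptibility in [0, 1]
    biomarker_label: pd.Series         # binary per line
    noise_sd: float
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "active_compounds": sorted(self.active_compounds),
            "effect_size": {
                "index": list(self.effect_size.index),
                "columns": list(self.effect_size.columns),
                "values": self.effect_size.to_numpy().tolist(),
            },
            "moa_assignment": self.moa_assignment,
            "moa_latent": {
                "index": list(self.moa_latent.index),
                "columns": list(self.moa_latent.columns),
                "values": self.moa_latent.to_numpy().tolist(),
            },
            "biomarker_label": self.biomarker_label.astype(int).to_dict(),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SyntheticExpressionTruth:
    """Planted ground truth behind a synthetic expression matrix."""

    deg_up: set[str]
    deg_down: set[str]
    corr_genes: dict[str, int]         # gene -> planted correlation sign (+1/-1)
    enriched_sets: dict[str, list[str]]
    response: pd.Series                # per-line response the corr genes track
    seed: int


def _compound_ids(n: int) -> list[str]:
    return [f"CMP{i:04d}" for i in range(n)]


def _line_ids(n: int) -> list[str]:
    return [f"LINE{i:02d}" for i in range(n)]


def generate_screen(
    n_compounds: int = DEFAULT_N_COMPOUNDS,
    n_lines: int = DEFAULT_N_LINES,
    moa_spec: dict[str, int] | None = None,
    frac_active: float = DEFAULT_FRAC_ACTIVE,
    effect_mu: float = DEFAULT_EFFECT_MU,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> tuple[DrugResponseMatrix, SyntheticScreenTruth]:
    """Generate a synthetic single-dose pooled screen with planted actives.

    ``moa_spec`` maps MOA label -> number of compounds carrying it, assigned
    from the front of the compound list; the planted active set is the first
    ``round(frac_active * n_compounds)`` compounds, so MOA-structured
    compounds are active by construction.  Remaining compounds are labelled
    ``"unannotated"``.  By default the actives are split evenly over four
    MOA blocks.

    Returns the screen plus its :class:`SyntheticScreenTruth`; the emitted
    logFC is ``effect_size[c, l] + Normal(0, noise_sd)`` where
    ``effect_size[c, l] = potency_c * latent[moa(c), l]`` for active
    compounds and 0 otherwise.
    """
    if n_compounds < 0 or n_lines < 0:
        raise ValueError("counts must be non-negative")
    if not 0 <= frac_active <= 1:
        raise ValueError("frac_active must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    compounds = _compound_ids(n_compounds)
    lines = _line_ids(n_lines)
    n_active = int(round(frac_active * n_compounds))

    if moa_spec is None:
        moa_spec = {}
        if n_active:
            per = max(1, n_active // 4)
            for b in range(min(4, n_active)):
                lo = b * per
                hi = n_active if b == 3 else min(n_active, (b + 1) * per)
                if hi > lo:
                    moa_spec[f"MOA_{'ABCD'[b]}"] = hi - lo
    if sum(moa_spec.values()) > n_compounds:
        raise ValueError("moa_spec assigns more compounds than exist")

    moa_assignment: dict[str, str] = {}
    cursor = 0
    for moa, count in moa_spec.items():
        for c in compounds[cursor : cursor + count]:
            moa_assignment[c] = moa
        cursor += count
    for c in compounds[cursor:]:
        moa_assignment[c] = "unannotated"

    moa_labels = list(dict.fromkeys(moa_assignment.values())) if compounds else []
    latent = pd.DataFrame(0.0, index=moa_labels, columns=lines)
    for moa in moa_labels:
        susceptible = rng.random(n_lines) < _LATENT_PROB
        magnitude = rng.uniform(*_LATENT_RANGE, size=n_lines)
        latent.loc[moa] = np.where(susceptible, magnitude, 0.0)

    active = set(compounds[:n_active])
    potency = np.minimum(effect_mu + _EFFECT_SPREAD * rng.standard_normal(n_compounds), -0.1)

    effect = pd.DataFrame(0.0, index=compounds, columns=lines)
    for i, c in enumerate(compounds):
        if c in active:
            effect.loc[c] = potency[i] * latent.loc[moa_assignment[c]].to_numpy()

    noise = rng.normal(0.0, noise_sd, size=(n_compounds, n_lines)) if noise_sd > 0 else 0.0
    values = pd.DataFrame(
        effect.to_numpy() + noise, index=compounds, columns=lines, dtype=float
    )

    categories = rng.choice(
        list(_CATEGORY_PROPS), size=n_compounds, p=list(_CATEGORY_PROPS.values())
    )
    compound_info = pd.DataFrame(
        {
            "name": compounds,
            "category": categories,
            "moa": [moa_assignment[c] for c in compounds],
        },
        index=pd.Index(compounds, name="compound_id"),
    )
    if moa_labels:
        biomarker = (latent.loc[moa_labels[0]] > 0).astype(int)
    else:
        biomarker = pd.Series(0, index=lines, dtype=int)
    line_info = pd.DataFrame(
        {
            "lineage": "upper_aerodigestive",
            "subtype": np.where(rng.random(n_lines) < 0.6, "OSCC", "non-OSCC"),
            "biomarker": biomarker.to_numpy() if n_lines else [],
        },
        index=pd.Index(lines, name="line_id"),
    )

    truth = SyntheticScreenTruth(
        active_compounds=active,
        effect_size=effect,
        moa_assignment=moa_assignment,
        moa_latent=latent,
        biomarker_label=biomarker,
        noise_sd=noise_sd,
        seed=seed,
    )
    return DrugResponseMatrix(values, compound_info, line_info), truth


def generate_expression(
    n_genes: int,
    lines: list[str],
    group_a: list[str],
    deg_frac: float = 0.05,
    deg_delta: float = 2.0,
    corr_spec: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticExpressionTruth]:
    """Generate a log2-scale expression matrix with planted structure.

    Plants ``round(deg_frac * n_genes)`` differential genes (half shifted up
    by ``deg_delta`` in ``group_a``, half down), and for every entry of
    ``corr_spec`` a gene generated as ``baseline + slope * response + noise``
    against an internally drawn per-line response vector (returned in the
    truth).  Values are clipped at 0 to respect the log2(TPM+1) >= 0 scale.
    """
    if not set(group_a) <= set(lines):
        raise ValueError("group_a must be a subset of lines")
    if not 0 <= deg_frac <= 1:
        raise ValueError("deg_frac must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    corr_spec = dict(corr_spec or {})

    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    extra = [g for g in corr_spec if g not in set(genes)]
    all_genes = genes + extra
    n_lines = len(lines)

    baseline = rng.uniform(4.0, 10.0, size=len(all_genes))
    values = np.tile(baseline[:, None], (1, n_lines))
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=(len(all_genes), n_lines))

    in_a = np.array([l in set(group_a) for l in lines])
    n_deg = int(round(deg_frac * n_genes))
    deg_genes = list(rng.choice(genes, size=n_deg, replace=False)) if n_deg else []
    half = n_deg // 2
    deg_up = set(deg_genes[:half]) if n_deg >= 2 else set(deg_genes)
    deg_down = set(deg_genes[half:]) if n_deg >= 2 else set()
    index_of = {g: i for i, g in enumerate(all_genes)}
    for g in deg_up:
        values[index_of[g], in_a] += deg_delta
    for g in deg_down:
        values[index_of[g], in_a] -= deg_delta

    response = pd.Series(rng.standard_normal(n_lines), index=lines, name="response")
    corr_signs: dict[str, int] = {}
    for g, slope in corr_spec.items():
        values[index_of[g]] = baseline[index_of[g]] + slope * response.to_numpy()
        if noise_sd > 0:
            values[index_of[g]] += rng.normal(0.0, noise_sd, size=n_lines)
        corr_signs[g] = 1 if slope > 0 else -1

    expr = pd.DataFrame(np.clip(values, 0.0, None), index=all_genes, columns=lines)
    enriched = {}
    if deg_up:
        enriched["PLANTED_UP"] = sorted(deg_up)
    if deg_down:
        enriched["PLANTED_DOWN"] = sorted(deg_down)
    truth = SyntheticExpressionTruth(
        deg_up=deg_up,
        deg_down=deg_down,
        corr_genes=corr_signs,
        enriched_sets=enriched,
        response=response,
        seed=seed,
    )
    return expr, truth


def generate_calibration_set(
    n_pos: int,
    n_neg: int,
    mu_pos: float = -1.8,
    mu_neg: float = -0.2,
    sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """Draw biomarker-positive / -negative logFC values for threshold calibration.

    Emulates the construction behind cutoff calibration on a drug with a known
    mutational biomarker of response: biomarker-positive lines respond
    (Normal(mu_pos, sd^2)), negative lines do not (Normal(mu_neg, sd^2)).
    Returns aligned (values, labels) Series; label 1 = biomarker positive.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one positive and one negative line")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    pos = mu_pos + (sd * rng.standard_normal(n_pos) if sd > 0 else np.zeros(n_pos))
    neg = mu_neg + (sd * rng.standard_normal(n_neg) if sd > 0 else np.zeros(n_neg))
    ids = _line_ids(n_pos + n_neg)
    values = pd.Series(np.concatenate([pos, neg]), index=ids, name="logfc")
    labels = pd.Series(
        np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)]), index=ids, name="biomarker"
    )
    return values, labels


def generate_differential_screen(
    n_compounds: int = 2000,
    n_selective: int = 0,
    n_in: int = 28,
    n_out: int = 100,
    shift: float = -1.5,
    noise_sd: float = 0.6,
    seed: int = 0,
) -> tuple[pd.DataFrame, set[str], list[str], list[str]]:
    """Two-cohort screen for differential-sensitivity testing.

    All compounds are Gaussian noise around 0; the first ``n_selective``
    compounds get an extra mean ``shift`` (< 0 = preferential killing) on the
    in-group lines only.  Returns (values, selective ids, in ids, out ids).
    """
    if n_selective > n_compounds:
        raise ValueError("n_selective cannot exceed n_compounds")
    rng = np.random.default_rng(seed)
    compounds = _compound_ids(n_compounds)
    in_lines = [f"IN{i:03d}" for i in range(n_in)]
    out_lines = [f"OUT{i:03d}" for i in range(n_out)]
    values = rng.normal(0.0, noise_sd, size=(n_compounds, n_in + n_out))
    values[:n_selective, :n_in] += shift
    frame = pd.DataFrame(values, index=compounds, columns=in_lines + out_lines)
    return frame, set(compounds[:n_selective]), in_lines, out_lines


def random_gene_sets(
    genes: list[str], n_sets: int, size: int, seed: int = 0, prefix: str = "RANDOM"
) -> dict[str, list[str]]:
    """Draw gene sets uniformly from ``genes`` (null sets for enrichment tests)."""
    rng = np.random.default_rng(seed)
    return {
        f"{prefix}_{i:03d}": sorted(rng.choice(genes, size=size, replace=False))
        for i in range(n_sets)
    }


def write_screen(drm: DrugResponseMatrix, truth: SyntheticScreenTruth, outdir) -> dict[str, Path]:
    """Serialize a synthetic screen in the same CSV dialects the readers consume.

    Emits matrix.csv (compounds x lines), line_info.csv, compound_info.csv
    and a truth.json sidecar; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.csv",
        "line_info": outdir / "line_info.csv",
        "compound_info": outdir / "compound_info.csv",
        "truth": outdir / "truth.json",
    }
    drm.values.to_csv(paths["matrix"], index_label="compound_id")
    li = drm.line_info if drm.line_info is not None else pd.DataFrame(index=drm.values.columns)
    li.rename_axis("row_name").reset_index().assign(ccle_name=li.index).to_csv(
        paths["line_info"], index=False
    )
    ci = drm.compound_info if drm.compound_info is not None else pd.DataFrame(
        {"name": drm.values.index}, index=drm.values.index
    )
    ci.rename_axis("column_name").reset_index().to_csv(paths["compound_info"], index=False)
    truth.to_json(paths["truth"])
    return paths
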