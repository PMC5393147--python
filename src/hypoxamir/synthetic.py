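"""Seeded generators for study-structured synthetic data with ground truth.

The generators emulate the statistical structure of a CRC cell-line hypoxia
screen: a large miRNA panel profiled across a panel of cell lines at three
oxygen tensions (normoxia 20.9%, hypoxia 1% and 0.2%), where between-cell-line
differences dominate the variance and a small fraction of features carry a
monotone expression change along the ordinal oxygen axis; a metabolite panel
with the same design; a miRNA→gene target network with pathway gene sets and
optionally planted target enrichment; and a small two-group tumour cohort
(responders vs non-responders to 5-FU) with survival times.

All generators are pure functions of their parameters and a seed, return the
planted truth alongside the data, and emit containers that pass datamodel
validation. Effects are additive on the log2 scale.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np

from .datamodel import ExpressionMatrix, PathwayDB, SampleMetadata, TargetTable

__all__ = [
    "PanelTruth",
    "NetworkTruth",
    "CohortTruth",
    "CELL_LINES",
    "simulate_mirna_panel",
    "simulate_metabolite_panel",
    "simulate_target_network",
    "simulate_tissue_cohort",
]

#: The six CRC lines of the panel (three colon, three rectal).
CELL_LINES = ("DLD-1", "HCT116", "HT29", "HT55", "SW837", "VACO4S")

#: Oxygen percentages corresponding to ordinal codes 0, 1, 2.
TENSION_PCT = {0: 20.9, 1: 1.0, 2: 0.2}


@dataclasses.dataclass
class PanelTruth:
    """Planted generative parameters for a simulated expression panel."""

    responsive_features: set[str]
    beta: dict[str, float]  # log2 units per ordinal oxygen step; 0 off-truth
    cellline_effects: dict[tuple[str, str], float]
    baseline: dict[str, float]
    noise_sd: float


@dataclasses.dataclass
class NetworkTruth:
    """Planted structure of a simulated target network."""

    planted_pathways: set[str]
    significant_mirnas: set[str]
    baseline_edge_prob: float
    planted_edge_prob: float


@dataclasses.dataclass
class CohortTruth:
    """Planted structure of a simulated two-group tumour cohort."""

    de_features: set[str]
    effect: float
    survival_years: dict[str, float]


def _panel(
    prefix: str,
    n_features: int,
    cell_lines: Sequence[str],
    tensions: Sequence[int],
    replicates: int,
    frac_responsive: float,
    effect_per_step: float,
    cellline_sd: float,
    noise_sd: float,
    seed: int,
) -> tuple[ExpressionMatrix, list[SampleMetadata], PanelTruth]:
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if len(set(cell_lines)) != len(cell_lines):
        raise ValueError("duplicate cell-line labels")
    if len(set(tensions)) < 2:
        raise ValueError("need at least two oxygen tensions")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not 0.0 <= frac_responsive <= 1.0:
        raise ValueError(f"frac_responsive must be in [0, 1], got {frac_responsive}")
    if min(cellline_sd, noise_sd) < 0:
        raise ValueError("standard deviations must be >= 0")

    rng = np.random.default_rng(seed)
    features = [f"{prefix}-{i + 1:04d}" for i in range(n_features)]
    n_responsive = int(round(frac_responsive * n_features))
    responsive = set(rng.choice(n_features, size=n_responsive, replace=False).tolist())

    baseline = rng.normal(8.0, 2.0, size=n_features)
    cl_eff = rng.normal(0.0, cellline_sd, size=(n_features, len(cell_lines)))
    beta = np.zeros(n_features)
    beta[list(responsive)] = effect_per_step

    sample_ids: list[str] = []
    metadata: list[SampleMetadata] = []
    cols: list[np.ndarray] = []
    for ci, line in enumerate(cell_lines):
        for t in tensions:
            for rep in range(1, replicates + 1):
                sid = f"{line}_O2c{t}_r{rep}"
                sample_ids.append(sid)
                metadata.append(
                    SampleMetadata(
                        sample_id=sid,
                        cell_line=line,
                        oxygen_pct=TENSION_PCT.get(int(t), float(t)),
                        oxygen_code=int(t),
                        replicate=rep,
                    )
                )
                noise = rng.normal(0.0, noise_sd, size=n_features) if noise_sd > 0 else 0.0
                cols.append(baseline + cl_eff[:, ci] + beta * t + noise)

    matrix = ExpressionMatrix(features, sample_ids, np.column_stack(cols), is_log=True)
    truth = PanelTruth(
        responsive_features={features[i] for i in responsive},
        beta={features[i]: float(beta[i]) for i in range(n_features)},
        cellline_effects={
            (features[i], line): float(cl_eff[i, ci])
            for i in range(n_features)
            for ci, line in enumerate(cell_lines)
        },
        baseline={features[i]: float(baseline[i]) for i in range(n_features)},
        noise_sd=noise_sd,
    )
    return matrix, metadata, truth


def simulate_mirna_panel(
    n_features: int = 1896,
    cell_lines: Sequence[str] = CELL_LINES,
    tensions: Sequence[int] = (0, 1, 2),
    replicates: int = 3,
    frac_responsive: float = 41 / 1896,
    effect_per_step: float = 1.0,
    cellline_sd: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[SampleMetadata], PanelTruth]:
    """Simulate a log2-scale miRNA array panel.

    The generative model is x = mu_f + c_{f,line} + beta_f * t + eps with
    mu_f ~ N(8, 2^2), cell-line offsets c ~ N(0, cellline_sd^2) and noise
    eps ~ N(0, noise_sd^2); beta_f = ``effect_per_step`` for the randomly
    drawn responsive subset and 0 elsewhere. Defaults plant 41 responsive
    features out of 1896 across six cell lines, three tensions and three
    replicates, with cell-line variance dominating.
    """
    return _panel(
        "miR-sim",
        n_features,
        cell_lines,
        tensions,
        replicates,
        frac_responsive,
        effect_per_step,
        cellline_sd,
        noise_sd,
        seed,
    )


def simulate_metabolite_panel(
    n_features: int = 200,
    cell_lines: Sequence[str] = CELL_LINES,
    tensions: Sequence[int] = (0, 1, 2),
    replicates: int = 3,
    frac_responsive: float = 92 / 200,
    effect_per_step: float = 1.0,
    cellline_sd: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[SampleMetadata], PanelTruth]:
    """Simulate a log2-scale metabolite panel (same generative family as the
    miRNA panel); defaults plant 92 altered metabolites out of 200."""
    return _panel(
        "met-sim",
        n_features,
        cell_lines,
        tensions,
        replicates,
        frac_responsive,
        effect_per_step,
        cellline_sd,
        noise_sd,
        seed,
    )


def simulate_target_network(
    mirna_ids: Sequence[str] | None = None,
    n_genes: int = 400,
    n_pathways: int = 10,
    pathway_size: int = 25,
    significant_set: Sequence[str] | None = None,
    planted_pathways: int = 1,
    baseline_edge_prob: float = 0.02,
    planted_edge_prob: float = 0.10,
    score_range: tuple[float, float] = (-3.0, -1.3),
    disjoint_pathways: bool = True,
    seed: int = 0,
) -> tuple[TargetTable, PathwayDB, NetworkTruth]:
    """Simulate a miRNA→gene target table with pathway sets and, optionally,
    planted enrichment.

    Edges are independent Bernoulli draws at ``baseline_edge_prob``; for each
    planted pathway, edges from the significant miRNA set to that pathway's
    genes are drawn at ``planted_edge_prob`` instead. mirSVR scores are
    uniform in ``score_range`` (default entirely below the −1.25 filter).
    """
    if mirna_ids is None:
        mirna_ids = [f"miR-sim-{i + 1:04d}" for i in range(200)]
    mirna_ids = list(mirna_ids)
    if significant_set is None:
        significant_set = mirna_ids[:40]
    significant_set = list(significant_set)
    unknown = set(significant_set) - set(mirna_ids)
    if unknown:
        raise ValueError(f"significant_set not within mirna_ids: {sorted(unknown)}")
    if planted_pathways > n_pathways:
        raise ValueError("planted_pathways cannot exceed n_pathways")
    if planted_edge_prob < baseline_edge_prob:
        raise ValueError("planted_edge_prob must be >= baseline_edge_prob")
    if disjoint_pathways and n_pathways * pathway_size > n_genes:
        raise ValueError("disjoint pathways require n_pathways * pathway_size <= n_genes")

    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]

    pathways: dict[str, list[str]] = {}
    if disjoint_pathways:
        perm = rng.permutation(n_genes)
        for p in range(n_pathways):
            idx = perm[p * pathway_size : (p + 1) * pathway_size]
            pathways[f"pathway_{p + 1:02d}"] = [genes[i] for i in idx]
    else:
        for p in range(n_pathways):
            idx = rng.choice(n_genes, size=pathway_size, replace=False)
            pathways[f"pathway_{p + 1:02d}"] = [genes[i] for i in idx]
    planted_names = set(list(pathways)[:planted_pathways])

    sig = set(significant_set)
    prob = np.full((len(mirna_ids), n_genes), baseline_edge_prob)
    gene_index = {g: j for j, g in enumerate(genes)}
    sig_rows = [i for i, m in enumerate(mirna_ids) if m in sig]
    for name in planted_names:
        cols = [gene_index[g] for g in pathways[name]]
        prob[np.ix_(sig_rows, cols)] = planted_edge_prob
    edges = rng.random((len(mirna_ids), n_genes)) < prob
    lo, hi = score_range
    scores = rng.uniform(lo, hi, size=edges.shape)

    records = [
        (mirna_ids[i], genes[j], float(scores[i, j]))
        for i, j in zip(*np.nonzero(edges))
    ]
    table = TargetTable(records)
    db = PathwayDB(pathways)
    truth = NetworkTruth(
        planted_pathways=planted_names,
        significant_mirnas=sig,
        baseline_edge_prob=baseline_edge_prob,
        planted_edge_prob=planted_edge_prob,
    )
    return table, db, truth


def simulate_tissue_cohort(
    n_responders: int = 5,
    n_nonresponders: int = 6,
    n_features: int = 800,
    frac_de: float = 33 / 800,
    effect: float = 2.0,
    noise_sd: float = 0.5,
    survival_coupling: bool = True,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[SampleMetadata], CohortTruth]:
    """Simulate a small 5-FU-treated tumour cohort with survival annotations.

    Responders survive > 5 years post-surgery (Uniform(5.5, 10)),
    non-responders < 5 years (Uniform(0.5, 4.5)). Planted differential
    features are shifted upward by ``effect`` log2 units in non-responders;
    with ``survival_coupling`` they additionally carry a −(effect/5)·survival
    term, so at zero noise every planted feature is exactly anti-monotone with
    survival (Spearman ρ = −1). Defaults give 11 tumours (six non-responders,
    five responders) and 33 planted features out of 800.
    """
    if min(n_responders, n_nonresponders) < 2:
        raise ValueError("both groups need at least 2 samples")
    if not 0.0 <= frac_de <= 1.0:
        raise ValueError(f"frac_de must be in [0, 1], got {frac_de}")
    rng = np.random.default_rng(seed)
    features = [f"miR-tis-{i + 1:04d}" for i in range(n_features)]
    n_de = int(round(frac_de * n_features))
    de_idx = set(rng.choice(n_features, size=n_de, replace=False).tolist())

    groups = ["responder"] * n_responders + ["non-responder"] * n_nonresponders
    survival = np.concatenate(
        [rng.uniform(5.5, 10.0, size=n_responders), rng.uniform(0.5, 4.5, size=n_nonresponders)]
    )
    baseline = rng.normal(8.0, 2.0, size=n_features)
    beta = np.zeros(n_features)
    beta[list(de_idx)] = effect
    coupling = (effect / 5.0) if survival_coupling else 0.0

    sample_ids = [f"tumour_{i + 1:02d}" for i in range(len(groups))]
    cols = []
    for k, group in enumerate(groups):
        shift = beta * (1.0 if group == "non-responder" else 0.0)
        noise = rng.normal(0.0, noise_sd, size=n_features) if noise_sd > 0 else 0.0
        cols.append(baseline + shift + noise - (coupling * survival[k]) * (beta != 0))
    values = np.column_stack(cols)

    metadata = [
        SampleMetadata(
            sample_id=sample_ids[k],
            cell_line="tumour",
            oxygen_pct=20.9,
            oxygen_code=0,
            replicate=1,
            group=groups[k],
        )
        for k in range(len(groups))
    ]
    matrix = ExpressionMatrix(features, sample_ids, values, is_log=True)
    truth = CohortTruth(
        de_features={features[i] for i in de_idx},
        effect=effect,
        survival_years={sample_ids[k]: float(survival[k]) for k in range(len(groups))},
    )
    return matrix, metadata, truth
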