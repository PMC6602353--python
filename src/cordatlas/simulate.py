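"""Synthetic UMI count matrices with planted ground truth.

The generator emulates the statistical structure of droplet scRNA-seq from the
embryonic neural tube so that every downstream stage of the pipeline can be
tested against a known answer:

* discrete progenitor-domain and neuronal-class identities along the
  dorsoventral axis, read out through the marker combinations of the shipped
  knowledge-matrix fixture;
* negative-binomial count noise with a fixed per-dataset dispersion
  (variance = mu + alpha * mu^2);
* temporally shifting population proportions across five embryonic stages
  (progenitor pool shrinking, motor neurons early, dI4/dI5 late);
* combinatorial domain-restricted expression patterns (a gene's mean is
  multiplied by 2^effect in the positive domain combination);
* co-expressed gene modules confined to planted cell subsets;
* a progenitor-to-neuron differentiation axis: per-cell latent time in [0, 1]
  with pan-progenitor markers ramping down and pan-neuronal markers ramping up
  log-linearly, optional transient pulses, and optional dorsoventrally biased
  trajectory genes;
* doublets built by summing the counts of two cells from distinct lineages;
* per-cell mitochondrial count fractions drawn from a Beta distribution.

The knowledge-matrix fixture is synthetic: the marker names follow standard
mouse dorsoventral patterning vocabulary, but the rows are constructed for
this simulator, not transcribed from any published supplementary table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from anndata import AnnData

from .identity import (
    KnowledgeMatrix,
    NEURON_LEVEL,
    PROGENITOR_LEVEL,
    TISSUE_LEVEL,
)
from .io_qc import make_count_matrix, write_10x

PROGENITOR_DOMAINS = (
    "FP", "p3", "pMN", "p2", "p1", "p0",
    "dp6", "dp5", "dp4", "dp3", "dp2", "dp1", "RP",
)
NEURON_CLASSES = (
    "V3", "MN", "V2a", "V2b", "V1", "V0",
    "dI6", "dI5", "dI4", "dI3", "dI2", "dI1",
)
NON_NEURAL_TISSUES = ("mesoderm", "neural_crest", "blood")
DEFAULT_STAGES = ("e9.5", "e10.5", "e11.5", "e12.5", "e13.5")

#: Dorsoventral position of each identity: a neuronal class shares the
#: position of the progenitor domain it derives from. Floor plate and roof
#: plate are progenitor-only positions.
DV_POSITION = {
    "FP": "FP", "RP": "RP",
    "p3": "p3", "V3": "p3",
    "pMN": "pMN", "MN": "pMN",
    "p2": "p2", "V2a": "p2", "V2b": "p2",
    "p1": "p1", "V1": "p1",
    "p0": "p0", "V0": "p0",
    "dp6": "dp6", "dI6": "dp6",
    "dp5": "dp5", "dI5": "dp5",
    "dp4": "dp4", "dI4": "dp4",
    "dp3": "dp3", "dI3": "dp3",
    "dp2": "dp2", "dI2": "dp2",
    "dp1": "dp1", "dI1": "dp1",
}

MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Co3",
    "mt-Atp6", "mt-Atp8", "mt-Cytb", "mt-Nd4", "mt-Nd5",
)

#: Signatures used to detect neural/mesodermal mixtures (doublets).
NEURAL_SIGNATURE = ("Sox2", "Tubb3", "Cdh2", "Sox21")
MESODERM_SIGNATURE = ("Meox1", "Twist1", "Tbx6", "Pdgfra")

_TISSUE_ROWS = (
    ("progenitor", ("Sox2", "Cdh2", "Sox21")),
    ("neuron", ("Tubb3", "Elavl3", "Cdh2", "Sox21")),
    # early neurons that still carry the pan-progenitor marker
    ("neuron", ("Sox2", "Tubb3", "Elavl3", "Cdh2", "Sox21")),
    ("mesoderm", ("Meox1", "Twist1", "Tbx6", "Pdgfra")),
    ("neural_crest", ("Sox10", "Ets1")),
    ("blood", ("Hbb-bs", "Klf1")),
)
_PROGENITOR_ROWS = (
    ("FP", ("Sox2", "Foxa2", "Shh")),
    ("p3", ("Sox2", "Nkx2-2", "Nkx2-9", "Nkx6-1")),
    ("pMN", ("Sox2", "Olig2", "Olig1", "Nkx6-1")),
    ("p2", ("Sox2", "Foxn4", "Vsx1", "Nkx6-1")),
    ("p1", ("Sox2", "Prdm12", "Nkx6-2")),
    ("p0", ("Sox2", "Dbx1", "Dbx2")),
    ("dp6", ("Sox2", "Pax3", "Gsx2", "Zic2")),
    ("dp5", ("Sox2", "Pax3", "Gsx1", "Ascl1")),
    ("dp4", ("Sox2", "Pax3", "Ptf1a", "Prdm13")),
    ("dp3", ("Sox2", "Pax3", "Olig3", "Msx3")),
    ("dp2", ("Sox2", "Pax3", "Neurog1", "Msx2")),
    ("dp1", ("Sox2", "Pax3", "Atoh1", "Msx1")),
    ("RP", ("Sox2", "Lmx1a", "Wnt1")),
)
_NEURON_ROWS = (
    ("V3", ("Tubb3", "Elavl3", "Sim1", "Uncx")),
    ("MN", ("Tubb3", "Elavl3", "Mnx1", "Isl1")),
    # motor neurons are also identifiable through the cholinergic transporter
    ("MN", ("Tubb3", "Elavl3", "Mnx1", "Slc18a3")),
    ("V2a", ("Tubb3", "Elavl3", "Vsx2", "Sox14")),
    ("V2b", ("Tubb3", "Elavl3", "Gata3", "Gata2")),
    ("V1", ("Tubb3", "Elavl3", "En1", "Pou6f2")),
    ("V0", ("Tubb3", "Elavl3", "Evx1", "Evx2")),
    ("dI6", ("Tubb3", "Elavl3", "Lbx1", "Wt1", "Dmrt3")),
    ("dI5", ("Tubb3", "Elavl3", "Lbx1", "Lmx1b", "Tlx3")),
    ("dI4", ("Tubb3", "Elavl3", "Lbx1", "Pax2", "Gbx1")),
    ("dI3", ("Tubb3", "Elavl3", "Isl1", "Tlx3")),
    ("dI2", ("Tubb3", "Elavl3", "Foxd3", "Pou4f1")),
    ("dI1", ("Tubb3", "Elavl3", "Lhx2", "Barhl1")),
)

#: Anchor genes of the four trajectory modules and their ramp direction.
TRAJECTORY_ANCHORS = (
    ("Sox2", "down"),    # pan-progenitor
    ("Tubb3", "up"),     # pan-neuronal
    ("Lin28a", "down"),  # early progenitor
    ("Fabp7", "up"),     # late progenitor / glial onset
)


def _read_text(path_or_text) -> str:
    try:
        p = Path(str(path_or_text))
        if p.exists():
            return p.read_text()
    except OSError:
        pass
    return str(path_or_text)


def make_knowledge_fixture() -> KnowledgeMatrix:
    """The shipped binary knowledge matrix (synthetic stand-in for a curated one).

    Three levels: coarse tissues, 13 progenitor domains (floor plate to roof
    plate) and 12 neuronal classes (V3 ... dI1). The neuron tissue and the MN
    class each own two alternative marker rows.
    """
    rows = []
    for level, defs in (
        (TISSUE_LEVEL, _TISSUE_ROWS),
        (PROGENITOR_LEVEL, _PROGENITOR_ROWS),
        (NEURON_LEVEL, _NEURON_ROWS),
    ):
        for identity, markers in defs:
            rows.append((identity, level, set(markers)))
    all_markers = sorted({m for _, _, ms in rows for m in ms})
    table = pd.DataFrame(
        [
            {"identity": ident, "level": level,
             **{m: int(m in ms) for m in all_markers}}
            for ident, level, ms in rows
        ]
    )
    return KnowledgeMatrix(table)


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPattern:
    """Genes whose mean is multiplied by 2^log2_effect in the positive domains."""

    genes: tuple
    positive: tuple
    log2_effect: float


@dataclass(frozen=True)
class PlantedModule:
    """A co-expressed gene group confined to a planted cell subset."""

    name: str
    genes: tuple
    cell_fraction: float
    domains: tuple | None = None  # None: eligible cells are all cells


@dataclass(frozen=True)
class PlantedPulse:
    """Transient up-then-down expression along latent time within one domain."""

    gene: str
    domain: str
    center: float
    width: float
    log2_amplitude: float


@dataclass
class SimConfig:
    """Study conditions of a simulated dataset. See the methods note for units."""

    stages: tuple = DEFAULT_STAGES
    n_cells_per_stage: int = 1000
    domain_proportions: dict | None = None  # stage -> {identity: fraction}
    n_genes: int = 400
    planted_patterns: tuple = ()
    planted_modules: tuple = ()
    planted_pulses: tuple = ()
    nb_dispersion: float = 0.3
    baseline_mean: float = 0.3
    doublet_rate: float = 0.0
    mito_beta: tuple = (2.5, 97.5)  # Beta(a, b) over the mito count fraction
    pseudotime_axis: bool = False
    progenitor_marker: str = "Sox2"
    neuron_marker: str = "Tubb3"
    n_trajectory_genes_per_module: int = 24
    n_dv_biased_trajectory_genes: int = 0
    marker_high_mean: float = 10.0
    marker_low_mean: float = 0.05
    module_high_mean: float = 5.0
    n_domains_progenitor: int = 13
    n_domains_neuron: int = 12
    seed: int = 0

    def proportions(self) -> dict:
        if self.domain_proportions is not None:
            return self.domain_proportions
        return default_domain_proportions(self.stages)

    def validate(self) -> None:
        props = self.proportions()
        known = set(PROGENITOR_DOMAINS) | set(NEURON_CLASSES) | set(NON_NEURAL_TISSUES)
        for stage in self.stages:
            if stage not in props:
                raise ValueError(f"no domain proportions for stage {stage}")
            p = props[stage]
            if abs(sum(p.values()) - 1.0) > 1e-9:
                raise ValueError(f"proportions at stage {stage} do not sum to 1")
            unknown = set(p) - known
            if unknown:
                raise ValueError(f"unknown identities in proportions: {unknown}")
        pattern_genes = {g for p in self.planted_patterns for g in p.genes}
        module_genes = {g for m in self.planted_modules for g in m.genes}
        if pattern_genes & module_genes:
            raise ValueError("pattern and module gene sets must be disjoint")
        for p in self.planted_patterns:
            if p.log2_effect <= 0:
                raise ValueError("planted effect sizes must be strictly positive")
        for m in self.planted_modules:
            if not 0 < m.cell_fraction <= 1:
                raise ValueError("module cell fractions must be in (0, 1]")
        if not 0 <= self.doublet_rate < 1:
            raise ValueError("doublet_rate must be in [0, 1)")
        if self.nb_dispersion < 0 or self.baseline_mean <= 0:
            raise ValueError("nb_dispersion must be >= 0 and baseline_mean > 0")
        if self.n_domains_progenitor != len(PROGENITOR_DOMAINS):
            raise ValueError("fixture defines 13 progenitor domains")
        if self.n_domains_neuron != len(NEURON_CLASSES):
            raise ValueError("fixture defines 12 neuronal classes")

    def to_yaml(self, path=None) -> str:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        text = yaml.safe_dump(plain(asdict(self)), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "SimConfig":
        raw = yaml.safe_load(_read_text(path_or_text))
        raw["stages"] = tuple(raw.get("stages", DEFAULT_STAGES))
        raw["planted_patterns"] = tuple(
            PlantedPattern(tuple(p["genes"]), tuple(p["positive"]), p["log2_effect"])
            for p in raw.get("planted_patterns", ())
        )
        raw["planted_modules"] = tuple(
            PlantedModule(
                m["name"], tuple(m["genes"]), m["cell_fraction"],
                tuple(m["domains"]) if m.get("domains") else None,
            )
            for m in raw.get("planted_modules", ())
        )
        raw["planted_pulses"] = tuple(
            PlantedPulse(
                p["gene"], p["domain"], p["center"], p["width"], p["log2_amplitude"]
            )
            for p in raw.get("planted_pulses", ())
        )
        raw["mito_beta"] = tuple(raw.get("mito_beta", (2.5, 97.5)))
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted per-cell and per-gene truth of a simulated dataset."""

    identities: list          # per cell: 1-tuple, or 2-tuple for doublets
    pseudotime: np.ndarray    # latent time in [0, 1]; NaN for non-neural cells
    doublet: np.ndarray       # boolean flags
    doublet_parents: dict     # cell index -> (parent index, parent index)
    gene_patterns: dict       # gene -> positive domain tuple
    gene_modules: dict        # gene -> module name
    module_cells: dict = field(default_factory=dict)  # module name -> cell indices

    @property
    def primary_identity(self) -> np.ndarray:
        return np.array([ids[0] for ids in self.identities], dtype=object)

    def to_json(self, path=None) -> str:
        payload = {
            "identities": [list(i) for i in self.identities],
            "pseudotime": [None if np.isnan(t) else float(t) for t in self.pseudotime],
            "doublet": [bool(d) for d in self.doublet],
            "doublet_parents": {str(k): list(v) for k, v in self.doublet_parents.items()},
            "gene_patterns": {g: list(p) for g, p in self.gene_patterns.items()},
            "gene_modules": dict(self.gene_modules),
            "module_cells": {k: [int(i) for i in v] for k, v in self.module_cells.items()},
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path_or_text) -> "GroundTruth":
        raw = json.loads(_read_text(path_or_text))
        return cls(
            identities=[tuple(i) for i in raw["identities"]],
            pseudotime=np.array(
                [np.nan if t is None else t for t in raw["pseudotime"]]
            ),
            doublet=np.array(raw["doublet"], dtype=bool),
            doublet_parents={
                int(k): tuple(v) for k, v in raw["doublet_parents"].items()
            },
            gene_patterns={g: tuple(p) for g, p in raw["gene_patterns"].items()},
            gene_modules=dict(raw["gene_modules"]),
            module_cells={
                k: np.array(v, dtype=int)
                for k, v in raw.get("module_cells", {}).items()
            },
        )


def default_domain_proportions(
    stages=DEFAULT_STAGES, mesoderm_fraction: float = 0.0
) -> dict:
    """Stage-resolved identity proportions emulating neural tube dynamics.

    The progenitor share of the neural compartment falls from ~72% to ~16%
    across the stages; progenitor domains are uniform; among neurons, motor
    neurons dominate early while dI4/dI5 expand late. An optional mesodermal
    contaminant fraction is constant across stages.
    """
    stages = tuple(stages)
    n = len(stages)
    prog_share = np.linspace(0.72, 0.16, n)
    out = {}
    for i, stage in enumerate(stages):
        neural = 1.0 - mesoderm_fraction
        props = {}
        for d in PROGENITOR_DOMAINS:
            props[d] = neural * prog_share[i] / len(PROGENITOR_DOMAINS)
        frac = i / max(n - 1, 1)
        weights = {}
        for c in NEURON_CLASSES:
            if c == "MN":
                weights[c] = 3.0 - 2.0 * frac
            elif c in ("dI4", "dI5"):
                weights[c] = 0.5 + 1.5 * frac
            else:
                weights[c] = 1.0
        total_w = sum(weights.values())
        for c in NEURON_CLASSES:
            props[c] = neural * (1.0 - prog_share[i]) * weights[c] / total_w
        if mesoderm_fraction > 0:
            props["mesoderm"] = mesoderm_fraction
        out[stage] = props
    return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _marker_high_map() -> dict:
    """Gene -> identities in which the marker is highly expressed."""
    high: dict[str, set] = {}
    for ident, markers in _PROGENITOR_ROWS + _NEURON_ROWS:
        for m in markers:
            high.setdefault(m, set()).add(ident)
    for gene in ("Cdh2", "Sox21"):
        high[gene] = set(PROGENITOR_DOMAINS) | set(NEURON_CLASSES)
    high["Meox1"] = high["Twist1"] = high["Tbx6"] = high["Pdgfra"] = {"mesoderm"}
    high["Sox10"] = high["Ets1"] = {"neural_crest"}
    high["Hbb-bs"] = high["Klf1"] = {"blood"}
    return high


def _log_ramp(t, lo, hi):
    return np.exp(np.log(lo) + np.clip(t, 0, 1) * (np.log(hi) - np.log(lo)))


def _trajectory_gene_names(cfg: SimConfig) -> dict:
    """Module name -> ramp gene names (anchor first)."""
    out = {}
    for anchor, _ in TRAJECTORY_ANCHORS:
        extra = [
            f"Pt{anchor}.{i + 1:02d}" for i in range(cfg.n_trajectory_genes_per_module)
        ]
        out[f"traj:{anchor}"] = [anchor, *extra]
    return out


def simulate_counts(config: SimConfig) -> tuple[AnnData, GroundTruth]:
    """Draw a UMI count matrix with planted structure; deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    props = config.proportions()
    km = make_knowledge_fixture()  # validates fixture identifiability
    marker_genes = list(km.marker_names)

    # --- cells ---------------------------------------------------------
    identities, stage_col, replicate_col = [], [], []
    for stage in config.stages:
        labels = sorted(props[stage])
        p = np.array([props[stage][l] for l in labels])
        draws = rng.choice(len(labels), size=config.n_cells_per_stage, p=p / p.sum())
        identities.extend(labels[i] for i in draws)
        stage_col.extend([stage] * config.n_cells_per_stage)
        replicate_col.extend(
            f"{stage}-r{1 + i % 2}" for i in range(config.n_cells_per_stage)
        )
    identities = np.array(identities, dtype=object)
    n_cells = len(identities)
    is_prog = np.isin(identities, PROGENITOR_DOMAINS)
    is_neur = np.isin(identities, NEURON_CLASSES)
    t = np.full(n_cells, np.nan)
    t[is_prog] = rng.uniform(0.0, 0.55, is_prog.sum())
    t[is_neur] = rng.uniform(0.45, 1.0, is_neur.sum())

    # --- gene universe -------------------------------------------------
    traj = _trajectory_gene_names(config) if config.pseudotime_axis else {}
    dv_biased = [
        f"PtSox2.dv{i + 1:02d}" for i in range(config.n_dv_biased_trajectory_genes)
    ]
    if dv_biased:
        if not traj:
            raise ValueError("dorsoventrally biased trajectory genes need the axis")
        traj["traj:Sox2"] = traj["traj:Sox2"] + dv_biased
    pattern_genes = [g for p in config.planted_patterns for g in p.genes]
    module_genes = [g for m in config.planted_modules for g in m.genes]
    pulse_genes = [p.gene for p in config.planted_pulses]
    traj_genes = [g for gs in traj.values() for g in gs if g not in marker_genes]
    structured = (
        marker_genes + traj_genes + pattern_genes + module_genes + pulse_genes
    )
    if len(set(structured)) != len(structured):
        raise ValueError("planted gene names collide")
    needed = len(structured) + len(MITO_GENES)
    if config.n_genes < needed:
        raise ValueError(f"n_genes={config.n_genes} < {needed} structured genes")
    filler = [f"Gm{20000 + i}" for i in range(config.n_genes - needed)]
    genes = structured + filler + list(MITO_GENES)
    gidx = {g: j for j, g in enumerate(genes)}

    # --- expected counts ------------------------------------------------
    mean = np.full((n_cells, len(genes)), config.baseline_mean)
    high = _marker_high_map()
    t_filled = np.where(np.isnan(t), 0.0, t)
    for m in marker_genes:
        j = gidx[m]
        col = np.full(n_cells, config.marker_low_mean)
        in_high = np.isin(identities, sorted(high.get(m, set())))
        col[in_high] = config.marker_high_mean
        if config.pseudotime_axis and m == config.progenitor_marker:
            col[is_prog] = _log_ramp(t_filled[is_prog] / 0.55, 12.0, 4.0)
            col[is_neur] = _log_ramp((t_filled[is_neur] - 0.45) / 0.55, 0.8, 0.02)
        elif config.pseudotime_axis and m == config.neuron_marker:
            col[is_neur] = _log_ramp((t_filled[is_neur] - 0.45) / 0.55, 8.0, 15.0)
            col[is_prog] = _log_ramp(t_filled[is_prog] / 0.55, 0.02, 0.8)
        mean[:, j] = col
    ramp_ranges = {"down": (6.0, 0.05), "up": (0.05, 6.0)}
    directions = dict(TRAJECTORY_ANCHORS)
    neural = is_prog | is_neur
    for mod_name, gs in traj.items():
        anchor = mod_name.split(":", 1)[1]
        lo, hi = ramp_ranges[directions[anchor]]
        for g in gs:
            if g in marker_genes or g in dv_biased:
                continue
            col = np.full(n_cells, config.marker_low_mean)
            col[neural] = _log_ramp(t_filled[neural], lo, hi)
            mean[:, gidx[g]] = col
    dv_domains = ("FP", "p3", "pMN")  # restriction used for planted DV bias
    for g in dv_biased:
        col = np.full(n_cells, config.marker_low_mean)
        col[neural] = _log_ramp(t_filled[neural], 6.0, 0.05)
        col[np.isin(identities, dv_domains)] *= 8.0
        mean[:, gidx[g]] = col
    for pat in config.planted_patterns:
        in_pos = np.isin(identities, pat.positive)
        for g in pat.genes:
            mean[in_pos, gidx[g]] = config.baseline_mean * 2.0 ** pat.log2_effect
    module_cells: dict[str, np.ndarray] = {}
    for mod in config.planted_modules:
        eligible = (
            np.flatnonzero(np.isin(identities, mod.domains))
            if mod.domains
            else np.arange(n_cells)
        )
        n_pick = max(1, int(round(mod.cell_fraction * len(eligible))))
        chosen = rng.choice(eligible, size=n_pick, replace=False)
        module_cells[mod.name] = np.sort(chosen)
        for g in mod.genes:
            col = np.full(n_cells, config.marker_low_mean)
            col[module_cells[mod.name]] = config.module_high_mean
            mean[:, gidx[g]] = col
    for pulse in config.planted_pulses:
        in_dom = identities == pulse.domain
        bump = np.exp(-((t_filled - pulse.center) ** 2) / (2 * pulse.width ** 2))
        col = np.full(n_cells, config.marker_low_mean)
        col[in_dom] = config.baseline_mean * (
            1.0 + (2.0 ** pulse.log2_amplitude - 1.0) * bump[in_dom]
        )
        mean[:, gidx[pulse.gene]] = col
    # mitochondrial counts reproduce a Beta-distributed per-cell fraction
    mito_frac = rng.beta(*config.mito_beta, size=n_cells)
    non_mito_total = mean[:, : len(genes) - len(MITO_GENES)].sum(axis=1)
    mito_mean = mito_frac / (1.0 - mito_frac) * non_mito_total / len(MITO_GENES)
    for k, g in enumerate(MITO_GENES):
        mean[:, gidx[g]] = mito_mean

    # --- sampling -------------------------------------------------------
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, scale=mean / shape)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mean)

    truth = GroundTruth(
        identities=[(i,) for i in identities],
        pseudotime=t,
        doublet=np.zeros(n_cells, dtype=bool),
        doublet_parents={},
        gene_patterns={
            g: tuple(pat.positive)
            for pat in config.planted_patterns
            for g in pat.genes
        },
        gene_modules={
            **{g: mod.name for mod in config.planted_modules for g in mod.genes},
            **{g: name for name, gs in traj.items() for g in gs},
        },
        module_cells=module_cells,
    )
    barcodes = [f"C{i + 1:06d}" for i in range(n_cells)]
    adata = make_count_matrix(
        sp.csr_matrix(counts), genes, barcodes, stage=stage_col,
        replicate=replicate_col,
    )
    if config.doublet_rate > 0:
        adata, truth = simulate_doublets(adata, truth, config.doublet_rate, rng=rng)
    return adata, truth


def dv_position_labels(identity_labels) -> np.ndarray:
    """Map identities to dorsoventral positions (non-neural labels pass through)."""
    return np.array(
        [DV_POSITION.get(l, str(l)) for l in identity_labels], dtype=object
    )


def lineage_groups(identity_labels) -> np.ndarray:
    """Coarse lineage of each identity: 'neural' for the fixture domains,
    otherwise the tissue name itself."""
    neural = set(PROGENITOR_DOMAINS) | set(NEURON_CLASSES) | {"progenitor", "neuron"}
    return np.array(
        ["neural" if l in neural else str(l) for l in identity_labels], dtype=object
    )


def simulate_doublets(
    adata: AnnData,
    truth: GroundTruth,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[AnnData, GroundTruth]:
    """Replace a ``rate`` fraction of cells by sums of two cross-lineage parents.

    Parents are drawn from distinct lineage groups (neural vs each non-neural
    tissue); the doublet's counts are the element-wise sum of the two parents'
    counts, so its total UMI equals the sum of the parents' totals.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = adata.n_obs
    new_truth = GroundTruth(
        identities=list(truth.identities),
        pseudotime=truth.pseudotime.copy(),
        doublet=truth.doublet.copy(),
        doublet_parents=dict(truth.doublet_parents),
        gene_patterns=dict(truth.gene_patterns),
        gene_modules=dict(truth.gene_modules),
        module_cells=dict(truth.module_cells),
    )
    if rate == 0:
        return adata.copy(), new_truth
    lineages = lineage_groups(truth.primary_identity)
    groups = np.unique(lineages)
    if len(groups) < 2:
        raise ValueError("doublet simulation needs at least two lineage groups")
    n_doublets = rng.binomial(n, rate)
    if n_doublets == 0:
        return adata.copy(), new_truth
    targets = rng.choice(n, size=n_doublets, replace=False)
    x = np.asarray(sp.csr_matrix(adata.X).todense())
    for cell in targets:
        a = int(rng.integers(n))
        other = np.flatnonzero(lineages != lineages[a])
        b = int(rng.choice(other))
        x[cell] = x[a] + x[b]
        new_truth.identities[cell] = (
            truth.identities[a][0], truth.identities[b][0]
        )
        new_truth.pseudotime[cell] = np.nan
        new_truth.doublet[cell] = True
        new_truth.doublet_parents[int(cell)] = (a, b)
    out = adata.copy()
    out.X = sp.csr_matrix(x)
    return out, new_truth


def write_dataset(path, adata: AnnData, truth: GroundTruth,
                  config: SimConfig | None = None) -> None:
    """Write the 10x triplet files plus truth.json (and the config as YAML)."""
    path = Path(path)
    write_10x(adata, path)
    truth.to_json(path / "truth.json")
    if config is not None:
        config.to_yaml(path / "config.yaml")


# ---------------------------------------------------------------------------
# benchmark presets — the planted study conditions used by tests and the
# acceptance script; sizes are analysis choices documented in the methods note
# ---------------------------------------------------------------------------

def preset_pattern_recovery(
    seed: int,
    n_cells: int = 2000,
    n_pattern_genes: int = 50,
    n_null_genes: int = 500,
    log2_effect: float = 3.0,
) -> SimConfig:
    """Progenitor-only dataset with planted combinatorial patterns.

    Each pattern gene gets its own positive combination of 1-6 of the 13
    progenitor domains (the minority, enriched side), drawn deterministically
    from the seed.
    """
    rng = np.random.default_rng(seed)
    patterns = []
    for i in range(n_pattern_genes):
        size = int(rng.integers(1, 7))
        pos = tuple(
            sorted(rng.choice(PROGENITOR_DOMAINS, size=size, replace=False))
        )
        patterns.append(
            PlantedPattern((f"Pat{i + 1:04d}",), pos, log2_effect)
        )
    uniform = {d: 1.0 / len(PROGENITOR_DOMAINS) for d in PROGENITOR_DOMAINS}
    km_markers = len(make_knowledge_fixture().marker_names)
    return SimConfig(
        stages=("e10.5",),
        n_cells_per_stage=n_cells,
        domain_proportions={"e10.5": uniform},
        n_genes=km_markers + n_pattern_genes + n_null_genes + len(MITO_GENES),
        planted_patterns=tuple(patterns),
        seed=int(rng.integers(2 ** 31)),
    )


def preset_identity_benchmark(
    seed: int, n_cells_per_stage: int = 2000, doublet_rate: float = 0.01
) -> SimConfig:
    """Five-stage dataset with a mesodermal contaminant and planted doublets."""
    return SimConfig(
        n_cells_per_stage=n_cells_per_stage,
        domain_proportions=default_domain_proportions(mesoderm_fraction=0.08),
        doublet_rate=doublet_rate,
        pseudotime_axis=True,
        seed=seed,
    )


def preset_module_benchmark(
    seed: int,
    n_cells: int = 800,
    n_modules: int = 5,
    genes_per_module: int = 40,
    n_noise_genes: int = 300,
) -> SimConfig:
    """Single-stage dataset with planted co-expression modules plus noise genes."""
    rng = np.random.default_rng(seed)
    modules = tuple(
        PlantedModule(
            name=f"M{k + 1}",
            genes=tuple(f"Mod{k + 1}.{i + 1:03d}" for i in range(genes_per_module)),
            cell_fraction=0.2,
        )
        for k in range(n_modules)
    )
    km_markers = len(make_knowledge_fixture().marker_names)
    needed = km_markers + n_modules * genes_per_module + n_noise_genes + len(MITO_GENES)
    props = default_domain_proportions(("e11.5",))
    return SimConfig(
        stages=("e11.5",),
        n_cells_per_stage=n_cells,
        domain_proportions=props,
        n_genes=needed,
        planted_modules=modules,
        seed=int(rng.integers(2 ** 31)),
    )


def preset_trajectory_benchmark(
    seed: int, n_cells_per_stage: int = 800
) -> SimConfig:
    """Neural-only dataset with the differentiation axis and planted pulses.

    The default size gives ~150 cells per progenitor domain: enough data at
    the sparse late-time end of each domain's window to constrain the spline
    boundary, which is where per-domain transient localization is limited.
    """
    # pulse centers sit inside the progenitor time window (t < 0.55), where
    # the per-domain profile is constrained by data on both sides of the peak;
    # the width matches a broad developmental transient — narrower pulses are
    # below the resolution of a 3-df spline over the domain's time window
    pulses = (
        PlantedPulse("Pulse.pMN", "pMN", center=0.35, width=0.15, log2_amplitude=5.0),
        PlantedPulse("Pulse.p0", "p0", center=0.35, width=0.15, log2_amplitude=5.0),
        PlantedPulse("Pulse.dp4", "dp4", center=0.35, width=0.15, log2_amplitude=5.0),
    )
    cfg = SimConfig(
        n_cells_per_stage=n_cells_per_stage,
        pseudotime_axis=True,
        n_dv_biased_trajectory_genes=2,
        planted_pulses=pulses,
        seed=seed,
    )
    km_markers = len(make_knowledge_fixture().marker_names)
    needed = (
        km_markers
        + 4 * cfg.n_trajectory_genes_per_module + 2  # ramp genes + anchors in markers
        + cfg.n_dv_biased_trajectory_genes
        + len(pulses)
        + len(MITO_GENES)
    )
    return replace(cfg, n_genes=max(cfg.n_genes, needed + 50))


def toy_qc_matrix() -> tuple[AnnData, list]:
    """Hand-countable four-cell fixture for the quality filter.

    With ``max_mito=0.06`` and ``min_genes=5``: cell C1 has 10% mitochondrial
    counts (fails), C2 detects 3 genes (fails), C3 and C4 pass. Returns the
    matrix and the expected retained barcodes.
    """
    genes = ["Ga", "Gb", "Gc", "Gd", "Ge", "Gf", "mt-Nd1"]
    counts = np.array(
        [
            [3, 3, 3, 3, 3, 3, 2],   # C1: total 20, 2 mito -> 10%
            [4, 4, 4, 0, 0, 0, 0],   # C2: 3 genes detected
            [5, 5, 5, 5, 5, 4, 1],   # C3: 7 genes, 1/30 mito
            [2, 2, 2, 2, 2, 0, 0],   # C4: 5 genes, no mito
        ]
    )
    adata = make_count_matrix(counts, genes, ["C1", "C2", "C3", "C4"])
    return adata, ["C3", "C4"]
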