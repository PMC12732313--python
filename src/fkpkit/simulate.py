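"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here from a
seeded :class:`numpy.random.Generator`: monofunctional and fused protein
families, ranked profile-HMM hit tables, trees carrying a single
domain-fusion gain (with optional losses), initial-rate kinetic datasets,
thermal melt curves, and a reference-anchored census alignment. Each
generator is a pure function of its configuration and seed, and each
returns the matching truth labels so downstream inference can be scored.

The fused ("FKP") architecture is modelled as an N-terminal
pyrophosphorylase (GFPP) domain joined by a short linker to a C-terminal
kinase (FUK) domain, the arrangement found in bifunctional
fucokinase/GDP-fucose pyrophosphorylases.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: profile-HMM models that diagnose each architecture
FUK_MODEL = "COG2605"
GFPP_MODEL = "PF07959"
FKP_MODEL = "PRK13412"
DECOY_MODELS = tuple(f"DECOY_{i:02d}" for i in range(1, 6))

__all__ = [
    "SimConfig",
    "TruthLabels",
    "KineticTruth",
    "MeltTruth",
    "CensusConfig",
    "ProteinSet",
    "gen_domain_families",
    "gen_hit_table",
    "gen_fusion_tree",
    "gen_rate_data",
    "gen_melt_curve",
    "gen_census_alignment",
    "write_fasta",
    "write_truth_manifest",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters for family / hit-table / tree generation."""

    seed: int = 0
    n_fuk: int = 5
    n_gfpp: int = 5
    n_fkp: int = 5
    domain_len_fuk: int = 400
    domain_len_gfpp: int = 450
    linker_len: int = 20
    substitution_rate: float = 0.15
    score_noise_sd: float = 0.0
    tree_n_tips: int = 16
    fusion_clade_size: int = 5
    loss_count: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_fuk, self.n_gfpp, self.n_fkp,
            self.domain_len_fuk, self.domain_len_gfpp, self.linker_len,
            self.tree_n_tips, self.fusion_clade_size, self.loss_count,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must lie in [0, 1)")
        if self.fusion_clade_size > self.tree_n_tips:
            raise ValueError("fusion_clade_size cannot exceed tree_n_tips")
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be >= 0")


@dataclass
class TruthLabels:
    """Ground truth attached to a generated dataset.

    ``family`` maps protein id -> "FUK" | "GFPP" | "FKP".  For trees,
    ``tip_state`` maps tip label -> 0/1 fusion state, ``gain_branch`` names
    the child node of the branch carrying the single 0->1 gain, and
    ``loss_branches`` the child nodes of 1->0 loss branches.
    """

    family: dict[str, str] = field(default_factory=dict)
    tip_state: dict[str, int] = field(default_factory=dict)
    gain_branch: Optional[str] = None
    loss_branches: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class KineticTruth:
    """True kinetic parameters behind a simulated rate dataset.

    KM and Ki in uM, kcat in 1/s, E0 in uM, noise_cv a fraction.
    """

    KM: float
    kcat: float
    E0: float
    Ki: Optional[float] = None
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.KM <= 0 or self.kcat <= 0 or self.E0 <= 0:
            raise ValueError("KM, kcat and E0 must be positive")
        if self.Ki is not None and self.Ki <= 0:
            raise ValueError("Ki must be positive when present")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass(frozen=True)
class MeltTruth:
    """True transitions behind a simulated thermal melt curve.

    ``transitions`` is a sequence of (midpoint degC, steepness 1/degC,
    amplitude AU).  The grid mirrors a qPCR thermal ramp (default
    20-95 degC in 0.5 degC steps).
    """

    transitions: tuple[tuple[float, float, float], ...] = ((50.0, 1.0, 500.0),)
    baseline: float = 100.0
    plateau_decay: float = 0.0
    grid_start: float = 20.0
    grid_stop: float = 95.0
    grid_step: float = 0.5
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if not 1 <= len(self.transitions) <= 3:
            raise ValueError("1-3 transitions supported")
        for mid, steep, amp in self.transitions:
            if not self.grid_start < mid < self.grid_stop:
                raise ValueError(f"midpoint {mid} outside the temperature grid")

    def temperatures(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


ProteinSet = dict[str, str]  # id -> residue string


# ---------------------------------------------------------------------------
# protein families
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))

def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    if hit.any():
        # uniform substitution to one of the 19 other residues
        for i in np.flatnonzero(hit):
            choices = AMINO_ACIDS[AMINO_ACIDS != arr[i]]
            arr[i] = rng.choice(choices)
    return "".join(arr)


def gen_domain_families(config: SimConfig) -> tuple[ProteinSet, TruthLabels]:
    """Generate FUK, GFPP and fused FKP families from common ancestors.

    Each monofunctional family is a star radiation from one random
    ancestor; fused proteins are point-mutated copies of
    ``GFPP_ancestor + linker + FUK_ancestor`` (pyrophosphorylase domain
    N-terminal, kinase domain C-terminal).
    """
    if config.domain_len_fuk == 0 or config.domain_len_gfpp == 0:
        raise ValueError("domain lengths must be positive")
    rng = np.random.default_rng(config.seed)
    fuk_anc = _random_protein(rng, config.domain_len_fuk)
    gfpp_anc = _random_protein(rng, config.domain_len_gfpp)
    linker = _random_protein(rng, config.linker_len)
    fkp_anc = gfpp_anc + linker + fuk_anc

    proteins: ProteinSet = {}
    truth = TruthLabels()
    for fam, anc, n in (
        ("FUK", fuk_anc, config.n_fuk),
        ("GFPP", gfpp_anc, config.n_gfpp),
        ("FKP", fkp_anc, config.n_fkp),
    ):
        for i in range(1, n + 1):
            pid = f"{fam.lower()}_{i:04d}"
            proteins[pid] = _mutate(rng, anc, config.substitution_rate)
            truth.family[pid] = fam
    return proteins, truth


# ---------------------------------------------------------------------------
# HMM hit tables
# ---------------------------------------------------------------------------

# noiseless mean bit scores per (true family, model); decoys score 30.
_SCORE_MEANS = {
    "FUK": {FUK_MODEL: 120.0, FKP_MODEL: 20.0, GFPP_MODEL: 15.0},
    "GFPP": {GFPP_MODEL: 120.0, FKP_MODEL: 25.0, FUK_MODEL: 18.0},
    "FKP": {FKP_MODEL: 150.0, FUK_MODEL: 130.0, GFPP_MODEL: 120.0},
}
_DECOY_MEAN = 30.0


def gen_hit_table(
    proteins: ProteinSet,
    truth: TruthLabels,
    score_noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate a ranked hmmscan hit table for generated proteins.

    Mean scores reflect the true architecture: a monofunctional kinase
    scores highest on COG2605, a monofunctional pyrophosphorylase on
    PF07959, and a fused protein scores high on all three diagnostic
    models with the full-length model PRK13412 on top.  Five decoy models
    keep the ranking nontrivial.  Gaussian noise of the given sd is added
    to every score; scores are floored at 0.
    """
    missing = [p for p in proteins if p not in truth.family]
    if missing:
        raise ValueError(f"unlabeled proteins: {missing[:5]}")
    rng = np.random.default_rng(seed)
    rows = []
    for pid in proteins:
        means = _SCORE_MEANS[truth.family[pid]]
        for model in (FUK_MODEL, GFPP_MODEL, FKP_MODEL) + DECOY_MODELS:
            mu = means.get(model, _DECOY_MEAN)
            score = mu + (rng.normal(0.0, score_noise_sd) if score_noise_sd else 0.0)
            rows.append((pid, model, max(score, 0.0)))
    return pd.DataFrame(rows, columns=["query_id", "model_id", "score"])


# ---------------------------------------------------------------------------
# fusion-history trees
# ---------------------------------------------------------------------------

def _random_bifurcating(
    rng: np.random.Generator, labels: list[str], namespace: dendropy.TaxonNamespace
) -> dendropy.Node:
    """Random binary subtree over `labels` by successive random joins."""
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = namespace.get_taxon(lab) or namespace.new_taxon(lab)
        nd.edge.length = round(float(rng.uniform(0.05, 0.5)), 6)
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = dendropy.Node()
        parent.edge.length = round(float(rng.uniform(0.05, 0.5)), 6)
        parent.add_child(left)
        parent.add_child(right)
        nodes.append(parent)
    return nodes[0]


def gen_fusion_tree(
    n_tips: int,
    fusion_clade_size: int,
    loss_count: int = 0,
    seed: int = 0,
) -> tuple[dendropy.Tree, TruthLabels]:
    """Simulate a rooted tree with a single fusion gain and optional losses.

    One internal branch carries the 0->1 gain of the fused architecture;
    ``loss_count`` distinct terminal branches inside the gained subtree
    carry 1->0 reversions.  Tips are ``t01 .. tNN``; internal nodes are
    labelled ``n1 ..`` in preorder so truth branches can be named.
    """
    if fusion_clade_size < 1:
        raise ValueError("fusion_clade_size must be >= 1")
    if n_tips < 2 or fusion_clade_size >= n_tips:
        raise ValueError("need fusion_clade_size < n_tips and n_tips >= 2")
    if loss_count >= fusion_clade_size:
        raise ValueError("losses must leave at least one fused tip")

    rng = np.random.default_rng(seed)
    labels = [f"t{i:02d}" for i in range(1, n_tips + 1)]
    perm = rng.permutation(n_tips)
    fused = sorted(labels[i] for i in perm[:fusion_clade_size])
    rest = sorted(labels[i] for i in perm[fusion_clade_size:])

    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    gained = _random_bifurcating(rng, fused, ns)
    outside = _random_bifurcating(rng, rest, ns)
    tree.seed_node.add_child(gained)
    tree.seed_node.add_child(outside)
    tree.seed_node.edge.length = None
    for k, nd in enumerate(tree.preorder_internal_node_iter(), start=1):
        nd.label = f"n{k}"
    tree.is_rooted = True

    truth = TruthLabels()
    truth.gain_branch = gained.label if gained.label else gained.taxon.label
    states = {lab: (1 if lab in fused else 0) for lab in labels}
    if loss_count:
        lost = [fused[i] for i in rng.choice(len(fused), size=loss_count, replace=False)]
        for lab in lost:
            states[lab] = 0
        truth.loss_branches = sorted(lost)
    truth.tip_state = states
    return tree, truth


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def mm_rate(S: np.ndarray, KM: float, kcat: float, E0: float) -> np.ndarray:
    """Michaelis-Menten initial rate, uM/s when E0 is in uM."""
    S = np.asarray(S, dtype=float)
    return kcat * E0 * S / (KM + S)


def substrate_inhibition_rate(
    S: np.ndarray, KM: float, kcat: float, Ki: float, E0: float
) -> np.ndarray:
    """Uncompetitive substrate-inhibition rate law v = kcat*E0*S/(KM + S + S^2/Ki)."""
    S = np.asarray(S, dtype=float)
    return kcat * E0 * S / (KM + S + S * S / Ki)


def gen_rate_data(
    truth: KineticTruth,
    substrate_concs: Sequence[float],
    n_reps: int = 3,
    model: Literal["mm", "substrate_inhibition"] = "mm",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate replicate initial rates at each substrate concentration.

    Noise is multiplicative Gaussian with coefficient of variation
    ``truth.noise_cv`` (the roughly constant-CV error of plate-reader
    assays), truncated at zero.  Columns: substrate_conc_uM, replicate,
    rate_uM_per_s.
    """
    S = np.asarray(list(substrate_concs), dtype=float)
    if (S <= 0).any():
        raise ValueError("substrate concentrations must be positive")
    if model == "mm":
        v = mm_rate(S, truth.KM, truth.kcat, truth.E0)
    elif model == "substrate_inhibition":
        if truth.Ki is None:
            raise ValueError("substrate_inhibition model requires Ki")
        v = substrate_inhibition_rate(S, truth.KM, truth.kcat, truth.Ki, truth.E0)
    else:
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_reps + 1):
        noise = rng.normal(1.0, truth.noise_cv, size=S.size) if truth.noise_cv else 1.0
        vr = np.maximum(v * noise, 0.0)
        rows.extend(zip(S, [rep] * S.size, vr))
    return pd.DataFrame(rows, columns=["substrate_conc_uM", "replicate", "rate_uM_per_s"])


# ---------------------------------------------------------------------------
# melt curves
# ---------------------------------------------------------------------------

def gen_melt_curve(
    truth: MeltTruth,
    seed: int = 0,
    replicate: int = 1,
    condition: str = "apo",
) -> pd.DataFrame:
    """Simulate a dye-fluorescence thermal melt curve on the truth grid.

    Each unfolding transition contributes a logistic sigmoid
    ``amplitude / (1 + exp(-steepness * (T - midpoint)))``; an optional
    linear post-peak decay emulates dye dissociation at high temperature.
    Columns: temp_C, fluorescence, replicate, condition.
    """
    T = truth.temperatures()
    F = np.full_like(T, truth.baseline, dtype=float)
    for mid, steep, amp in truth.transitions:
        F = F + amp / (1.0 + np.exp(-steep * (T - mid)))
    if truth.plateau_decay:
        last_mid = max(m for m, _, _ in truth.transitions)
        ramp = np.clip(T - (last_mid + 5.0), 0.0, None)
        F = F - truth.plateau_decay * ramp
    if truth.noise_sd:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, truth.noise_sd, size=T.size)
    return pd.DataFrame(
        {"temp_C": T, "fluorescence": F,
         "replicate": replicate, "condition": condition}
    )


# ---------------------------------------------------------------------------
# census alignment (conservation module fixture generator)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CensusConfig:
    """Synthetic reference-anchored alignment for the conservation census.

    Emulates an FKP family alignment in which a subset of rows lacks the
    N-terminal region entirely (gap-prefixed rows, to be excluded), the
    pyrophosphorylase-domain reference positions are only moderately
    conserved — and almost all of that loss is concentrated in one clade
    ("C") — while the kinase-domain positions are nearly invariant.
    """

    n_rows: int = 186
    n_gap_prefixed: int = 15
    ref_len: int = 800
    gap_prefix_cols: int = 200
    # reference-anchored positions: residue letter + 1-based position
    gfpp_positions: tuple[str, ...] = ("G75", "R79", "K88")
    kinase_positions: tuple[str, ...] = ("R597", "D606", "D767")
    clade_counts: tuple[int, ...] = (45, 46, 95)  # clades A, B, C over all rows
    p_gfpp_cladeC: float = 0.18
    p_gfpp_other: float = 0.96
    p_kinase: float = 0.995
    background_identity: float = 0.8

    def __post_init__(self) -> None:
        if self.n_gap_prefixed >= self.n_rows:
            raise ValueError("gap-prefixed rows must be a strict subset")
        if sum(self.clade_counts) != self.n_rows:
            raise ValueError("clade_counts must sum to n_rows")


def _parse_pos(token: str) -> tuple[str, int]:
    return token[0], int(token[1:])


def gen_census_alignment(
    config: CensusConfig = CensusConfig(), seed: int = 0
) -> tuple[dict[str, str], dict[str, str], str]:
    """Build (alignment rows, clade labels, reference id).

    The alignment is gap-free except for the designated gap-prefixed rows,
    which carry gaps across the first ``gap_prefix_cols`` columns (past the
    last pyrophosphorylase-domain anchor) and are the rows the exclusion
    rule should remove.  Gap-prefixed rows are drawn from clade C.
    """
    rng = np.random.default_rng(seed)
    ref_id = "TxFKP_ref"
    ref = list(_random_protein(rng, config.ref_len))
    anchors: dict[int, str] = {}
    for token in config.gfpp_positions + config.kinase_positions:
        residue, pos = _parse_pos(token)
        ref[pos - 1] = residue
        anchors[pos] = residue
    last_gfpp = max(_parse_pos(t)[1] for t in config.gfpp_positions)
    if config.gap_prefix_cols <= last_gfpp:
        raise ValueError("gap prefix must extend past the last GFPP anchor")

    clades = []
    for name, n in zip("ABC", config.clade_counts):
        clades.extend([name] * n)
    rng.shuffle(clades)  # type: ignore[arg-type]

    # gap-prefixed rows come from clade C (the clade with N-terminal loss)
    c_rows = [i for i, c in enumerate(clades) if c == "C"]
    gap_rows = set(
        int(i) for i in rng.choice(c_rows, size=config.n_gap_prefixed, replace=False)
    )

    rows: dict[str, str] = {ref_id: "".join(ref)}
    clade_of: dict[str, str] = {ref_id: "B"}
    gfpp_cols = {_parse_pos(t)[1] - 1 for t in config.gfpp_positions}
    kin_cols = {_parse_pos(t)[1] - 1 for t in config.kinase_positions}
    for i in range(config.n_rows):
        rid = f"fkp_{i + 1:04d}"
        clade = clades[i]
        seq = []
        for c in range(config.ref_len):
            r = ref[c]
            if c in gfpp_cols:
                p = config.p_gfpp_cladeC if clade == "C" else config.p_gfpp_other
            elif c in kin_cols:
                p = config.p_kinase
            else:
                p = config.background_identity
            if rng.random() < p:
                seq.append(r)
            else:
                seq.append(str(rng.choice(AMINO_ACIDS[AMINO_ACIDS != r])))
        if i in gap_rows:
            seq[: config.gap_prefix_cols] = ["-"] * config.gap_prefix_cols
        rows[rid] = "".join(seq)
        clade_of[rid] = clade
    return rows, clade_of, ref_id


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def fasta_string(proteins: ProteinSet, width: int = 60) -> str:
    chunks = []
    for pid, seq in proteins.items():
        chunks.append(f">{pid}\n")
        for i in range(0, len(seq), width):
            chunks.append(seq[i : i + width] + "\n")
    return "".join(chunks)


def write_fasta(proteins: ProteinSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(fasta_string(proteins))


def truth_manifest_string(seed: int, **truths) -> str:
    """Seed plus all truth objects as one YAML document."""
    payload: dict = {"seed": seed}
    for key, val in truths.items():
        if dataclasses.is_dataclass(val) and not isinstance(val, type):
            payload[key] = dataclasses.asdict(val)
        else:
            payload[key] = val
    return yaml.safe_dump(payload, sort_keys=True)


def write_truth_manifest(path, seed: int, **truths) -> None:
    with open(path, "w") as fh:
        fh.write(truth_manifest_string(seed, **truths))
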