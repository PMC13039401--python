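"""Seeded synthetic inputs for every pipeline stage.

Four generators emulate the statistical structure of the real inputs,
each emitting machine-readable ground truth alongside its data so the
pipeline can be tested closed-loop:

* topology tables with a controllable planted fraction of "short-loop"
  proteins (longest cytosolic extension < 20 aa);
* aligned homolog families with polar-cap / hydrophobic-core / polar-cap
  TM architecture and separately tunable TM1 and TM2 core lengths;
* ideal poly-Leu helix bundles (canonical 1.5 Å rise, 100° twist per
  residue, reduced side chains) with one planted polar residue on a
  chosen face at mid-membrane;
* noisy exponential decay curves from either kinetic model.

Every generator takes the master seed and a fixed stream index, so
adding a generator never perturbs the draws of another
(``default_rng([seed, stream])``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .kinetics import DecayCurve, _eval_model
from .stretch import AlignedFamily
from .topology import Segment, TopologySegmentTable

__all__ = [
    "TopologySimConfig", "FamilySimConfig", "BundleSimConfig",
    "DecaySimConfig", "SyntheticConfig",
    "gen_topology_table", "gen_family_msa", "gen_helix_bundle",
    "gen_decay_curves", "inject_gap_columns",
]

_STREAMS = {"topology": 0, "family": 1, "bundle": 2, "decay": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


# -- topology tables --------------------------------------------------------

@dataclass(frozen=True)
class TopologySimConfig:
    """Planted short-loop probability ``p_short`` is the ground truth the
    loop pipeline must recover.  Loop lengths are geometric (right-skewed,
    like observed loop-length distributions); long loops get an extra
    offset past the 20-aa threshold."""

    n_proteins: int = 500
    p_short: float = 0.21
    tm_mean: float = 6.0           # mean TM count (>= 2 enforced)
    loop_mean_short: float = 8.0   # mean of short-regime loop lengths
    loop_mean_long: float = 40.0
    tm_len: int = 21
    pass_fraction: float = 0.8     # fraction passing all confidence filters

    def __post_init__(self):
        if not 0 <= self.p_short <= 1:
            raise ValueError("p_short must be in [0, 1]")
        if not 0 <= self.pass_fraction <= 1:
            raise ValueError("pass_fraction must be in [0, 1]")


def _geometric_capped(rng, mean, low, high):
    """Geometric draw with given mean, clipped into [low, high]."""
    p = 1.0 / max(mean, 1.0)
    return int(np.clip(rng.geometric(p), low, high))


def gen_topology_table(
    config: TopologySimConfig = TopologySimConfig(), seed: int = 0,
) -> tuple[list[TopologySegmentTable], list[dict]]:
    """Generate topology records plus per-protein ground truth.

    With probability ``p_short`` every cytosolic segment of a protein is
    drawn below 20 aa (possibly absent); otherwise at least one cytosolic
    segment is >= 20 aa.  Confidence grades are assigned so that
    ``pass_fraction`` of records pass all three filters.
    """
    rng = _rng(seed, "topology")
    records: list[TopologySegmentTable] = []
    truth: list[dict] = []
    for i in range(config.n_proteins):
        n_tm = max(2, int(rng.poisson(config.tm_mean - 2)) + 2)
        is_short = bool(rng.random() < config.p_short)

        # loop/tail lengths for the n_tm+1 non-membrane slots
        n_slots = n_tm + 1
        # first non-membrane label alternates thereafter
        first_cyto = bool(rng.random() < 0.5)
        labels = ["cytosolic" if (j % 2 == 0) == first_cyto
                  else "extracytosolic" for j in range(n_slots)]
        # every cytosolic slot starts in the short regime (< 20 aa);
        # non-short proteins get one slot promoted past the threshold below
        lengths = []
        for j in range(n_slots):
            if labels[j] == "cytosolic":
                lengths.append(
                    _geometric_capped(rng, config.loop_mean_short, 1, 19))
            else:
                lengths.append(_geometric_capped(rng, 12.0, 1, 200))
        # terminal tails may be absent entirely
        for j in (0, n_slots - 1):
            if rng.random() < 0.3:
                lengths[j] = 0

        cyto_slots = [j for j in range(n_slots) if labels[j] == "cytosolic"]
        if not is_short and cyto_slots:
            # plant one long cytosolic extension (>= 20 aa)
            j = int(rng.choice(cyto_slots))
            lengths[j] = 20 + _geometric_capped(
                rng, config.loop_mean_long, 0, 400)
        if not is_short and not cyto_slots:
            is_short = True  # no cytosolic slot at all -> short by absence

        # only terminal slots may be absent, so two membrane segments are
        # never adjacent (internal loops are always >= 1 residue)
        repacked: list[Segment] = []
        pos = 1
        for j in range(n_slots):
            if lengths[j] > 0:
                repacked.append(Segment(labels[j], pos,
                                        pos + lengths[j] - 1))
                pos += lengths[j]
            if j < n_tm:
                repacked.append(Segment("membrane", pos,
                                        pos + config.tm_len - 1))
                pos += config.tm_len

        passes = bool(rng.random() < config.pass_fraction)
        if passes:
            orientation = "high"
            tm_quality = str(rng.choice(["high", "medium"]))
            termini = True
        else:
            fail = int(rng.integers(0, 3))
            orientation = "medium" if fail == 0 else "high"
            tm_quality = "low" if fail == 1 else "high"
            termini = fail != 2
            if fail == 0 and rng.random() < 0.3:
                orientation = "low"

        rec = TopologySegmentTable(
            protein_id=f"SYN{i:05d}", segments=repacked,
            orientation_quality=orientation, tm_count_quality=tm_quality,
            termini_certain=termini)
        rec.validate()
        records.append(rec)
        longest = max((s.length for s in repacked
                       if s.label == "cytosolic"), default=0)
        truth.append({
            "protein_id": rec.protein_id,
            "passes_filters": passes,
            "is_short_true": longest < 20,
            "longest_cytosolic_true": longest,
        })
    return records, truth


# -- aligned homolog families ----------------------------------------------

HYDROPHOBIC_BG = "LIVFMA"
POLAR_CAP = "KRNQHDE"


@dataclass(frozen=True)
class FamilySimConfig:
    """Polar-cap / hydrophobic-core / polar-cap TM architecture.

    Core lengths are rounded normal draws; defaults plant the observed
    family architecture (TM1 core near 15 aa, TM2 near 20 aa, mirroring
    the short-TM1 signature of the protease family analyzed)."""

    n_seqs: int = 94
    tm1_core_mean: float = 15.0
    tm1_core_sd: float = 1.5
    tm2_core_mean: float = 20.0
    tm2_core_sd: float = 2.0
    cap_len: int = 2
    linker_mean: float = 8.0
    substitution_rate: float = 0.0   # per-core-position polar contamination
    n_gap_columns: int = 0

    def __post_init__(self):
        if self.n_seqs < 1:
            raise ValueError("n_seqs must be >= 1")


def _core_len(rng, mean, sd, low=4):
    return max(low, int(round(rng.normal(mean, sd))))


def gen_family_msa(
    config: FamilySimConfig = FamilySimConfig(), seed: int = 0,
) -> tuple[AlignedFamily, list[dict]]:
    """Build an aligned family with planted TM core lengths.

    Each sequence is linker | cap·core·cap (TM1) | linker | cap·core·cap
    (TM2) | linker; blocks are right-padded with gaps to the family
    maximum, so the TM column ranges are exact block boundaries and
    per-sequence gaps fall inside the TM regions.  Ground truth records
    the planted core lengths.
    """
    rng = _rng(seed, "family")
    truth: list[dict] = []
    parts: list[dict] = []
    for i in range(config.n_seqs):
        core1 = _core_len(rng, config.tm1_core_mean, config.tm1_core_sd)
        core2 = _core_len(rng, config.tm2_core_mean, config.tm2_core_sd)

        def cap():
            return "".join(rng.choice(list(POLAR_CAP), config.cap_len))

        def stretch(n):
            residues = list(rng.choice(list(HYDROPHOBIC_BG), n))
            if config.substitution_rate > 0:
                for j in range(n):
                    if rng.random() < config.substitution_rate:
                        residues[j] = str(rng.choice(list(POLAR_CAP)))
            return "".join(residues)

        def linker():
            n = _geometric_capped(rng, config.linker_mean, 2, 40)
            alphabet = list("GSTPAEDKRQN")
            return "".join(rng.choice(alphabet, n))

        parts.append({
            "id": f"hom{i:03d}",
            "blocks": [linker(), cap() + stretch(core1) + cap(), linker(),
                       cap() + stretch(core2) + cap(), linker()],
        })
        truth.append({"seq_id": f"hom{i:03d}",
                      "tm1_core_true": core1, "tm2_core_true": core2})

    widths = [max(len(p["blocks"][b]) for p in parts) for b in range(5)]
    sequences = []
    for p in parts:
        padded = [p["blocks"][b].ljust(widths[b], "-") for b in range(5)]
        sequences.append((p["id"], "".join(padded)))

    starts = np.cumsum([0] + widths[:-1]) + 1
    tm_regions = {
        "TM1": (int(starts[1]), int(starts[1] + widths[1] - 1)),
        "TM2": (int(starts[3]), int(starts[3] + widths[3] - 1)),
    }
    fam = AlignedFamily(sequences, tm_regions,
                        reference_id=parts[0]["id"], numbering_offset=0)
    if config.n_gap_columns > 0:
        fam = inject_gap_columns(fam, config.n_gap_columns, rng)
    fam.validate()
    return fam, truth


def inject_gap_columns(family: AlignedFamily, n: int,
                       rng: np.random.Generator) -> AlignedFamily:
    """Insert ``n`` all-gap columns at random positions, shifting the TM
    column ranges accordingly (stretch lengths must be unaffected)."""
    width = family.width
    positions = sorted(rng.integers(0, width + 1, size=n).tolist())
    sequences = []
    for seq_id, seq in family.sequences:
        chars = list(seq)
        for shift, pos in enumerate(positions):
            chars.insert(pos + shift, "-")
        sequences.append((seq_id, "".join(chars)))
    regions = {}
    for name, (lo, hi) in family.tm_regions.items():
        lo_new = lo + sum(1 for p in positions if p < lo)
        hi_new = hi + sum(1 for p in positions if p <= hi - 1)
        regions[name] = (lo_new, hi_new)
    return AlignedFamily(sequences, regions, family.reference_id,
                         family.numbering_offset)


# -- helix bundles ----------------------------------------------------------

HELIX_RISE = 1.5        # A per residue
HELIX_TWIST = 100.0     # degrees per residue
CA_RADIUS = 2.3         # A, canonical alpha-helix CA radius
#: distance of the reduced side-chain pseudo-atom from CA, per residue
SC_DISTANCE = {"LEU": 2.6, "GLN": 3.2}
SC_ATOM = {"LEU": ("CG", "C"), "GLN": ("NE2", "N")}


@dataclass(frozen=True)
class BundleSimConfig:
    """Ideal parallel helix bundle with one planted polar residue.

    ``plant_face`` chooses whether the planted residue's side chain points
    away from the bundle axis (lipid-facing) or toward it (buried).  The
    default 8 Å axis spacing is tighter than full-atom helix packing
    (~9.5 Å) because the reduced side-chain representation carries less
    bulk; it produces the same buried/exposed contrast by construction."""

    n_helices: int = 4
    n_res: int = 30
    spacing: float = 8.0           # A between adjacent helix axes
    plant_residue: str | None = "GLN"
    plant_helix: int = 0
    plant_face: str = "outward"    # 'outward' | 'inward'

    def __post_init__(self):
        if self.n_helices < 1:
            raise ValueError("n_helices must be >= 1")
        if self.plant_face not in ("outward", "inward"):
            raise ValueError("plant_face must be 'outward' or 'inward'")
        if self.n_helices >= 2 and self.spacing < 2 * CA_RADIUS + 2.0:
            raise ValueError(
                f"spacing {self.spacing} A too small for non-clashing "
                f"helices")


def _bundle_radius(n_helices: int, spacing: float) -> float:
    if n_helices == 1:
        return 0.0
    return spacing / (2.0 * math.sin(math.pi / n_helices))


def gen_helix_bundle(
    config: BundleSimConfig = BundleSimConfig(), seed: int = 0,
) -> tuple[struc.AtomArray, dict]:
    """Generate an ideal poly-Leu bundle (membrane normal = z) plus the
    planted-residue ground truth.

    Residues carry a reduced representation: backbone N/CA/C/O placed on
    canonical helix geometry and a single side-chain pseudo-atom at the
    residue's side-chain centroid distance, pointing radially away from
    the helix axis.  The planted residue (default Gln, via an N
    pseudo-atom) sits at the mid-slab position whose side chain best
    matches the requested face.
    """
    del seed  # geometry is deterministic; signature kept for uniformity
    cfg = config
    R = _bundle_radius(cfg.n_helices, cfg.spacing)
    z0 = -(cfg.n_res - 1) * HELIX_RISE / 2.0  # center bundle on z = 0

    atoms: list[struc.Atom] = []
    truth: dict = {}
    chains = [chr(ord("A") + h) for h in range(cfg.n_helices)]
    for h in range(cfg.n_helices):
        phi = 2 * math.pi * h / cfg.n_helices
        hx, hy = R * math.cos(phi), R * math.sin(phi)
        outward = np.array([math.cos(phi), math.sin(phi), 0.0])
        if cfg.n_helices == 1:
            outward = np.array([1.0, 0.0, 0.0])

        # choose the planted position on this helix (mid-slab, best face)
        plant_idx = -1
        if cfg.plant_residue and h == cfg.plant_helix:
            mid = [i for i in range(cfg.n_res)
                   if abs(z0 + i * HELIX_RISE) <= 4.0]
            sign = 1.0 if cfg.plant_face == "outward" else -1.0

            def radial(i):
                a = math.radians(i * HELIX_TWIST)
                u = np.array([math.cos(a), math.sin(a), 0.0])
                return float(np.dot(u, outward)) * sign

            plant_idx = max(mid, key=radial)

        for i in range(cfg.n_res):
            ang = math.radians(i * HELIX_TWIST)
            u = np.array([math.cos(ang), math.sin(ang), 0.0])
            z = z0 + i * HELIX_RISE
            ca = np.array([hx, hy, 0.0]) + CA_RADIUS * u + np.array([0, 0, z])
            res_name = ("GLN" if i == plant_idx else "LEU")
            res_id = i + 1

            def add(name, element, coord):
                atom = struc.Atom(coord, chain_id=chains[h], res_id=res_id,
                                  res_name=res_name, atom_name=name,
                                  element=element, hetero=False)
                atoms.append(atom)

            # crude backbone ring around the helix axis
            ang_n = math.radians(i * HELIX_TWIST - 28.0)
            ang_c = math.radians(i * HELIX_TWIST + 26.0)
            n_pos = (np.array([hx, hy, 0.0]) + 1.6 * np.array(
                [math.cos(ang_n), math.sin(ang_n), 0.0])
                + np.array([0, 0, z - 0.8]))
            c_pos = (np.array([hx, hy, 0.0]) + 1.7 * np.array(
                [math.cos(ang_c), math.sin(ang_c), 0.0])
                + np.array([0, 0, z + 0.9]))
            o_pos = c_pos + np.array([0.0, 0.0, 1.23])
            add("N", "N", n_pos)
            add("CA", "C", ca)
            add("C", "C", c_pos)
            add("O", "O", o_pos)
            cb = ca + 1.53 * u
            add("CB", "C", cb)
            sc_name, sc_elem = SC_ATOM[res_name]
            sc = ca + SC_DISTANCE[res_name] * u
            add(sc_name, sc_elem, sc)

            if i == plant_idx:
                truth = {
                    "chain_id": chains[h], "res_id": res_id,
                    "res_name": res_name, "face": cfg.plant_face,
                    "sidechain_z": float(sc[2]),
                }

    array = struc.array(atoms)
    return array, truth


# -- decay curves -----------------------------------------------------------

@dataclass(frozen=True)
class DecaySimConfig:
    """Noisy fraction-remaining curves.

    Defaults state the observed world for a stable-fraction decay: 60% of
    the pool degraded with a ~40 min half-life, 40% stable; seven
    timepoints over two hours; densitometry noise sigma = 0.05."""

    model: str = "single_plateau"
    params: tuple[tuple[str, float], ...] = (
        ("A", 0.6), ("k", math.log(2) / 40.0), ("C", 0.4))
    n_timepoints: int = 7
    t_max: float = 120.0
    sigma: float = 0.05
    n_replicates: int = 3

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(self.params)


def gen_decay_curves(
    config: DecaySimConfig = DecaySimConfig(), seed: int = 0,
) -> tuple[list[DecayCurve], dict]:
    """Model-evaluated curves plus Gaussian noise, clipped at 0 and
    normalized so each replicate's t = 0 point is 1."""
    rng = _rng(seed, "decay")
    times = np.linspace(0.0, config.t_max, config.n_timepoints)
    truth = {"model": config.model, "params": config.param_dict,
             "sigma": config.sigma, "times": times.tolist()}
    ideal = _eval_model(config.model, config.param_dict, times)
    curves = []
    for r in range(config.n_replicates):
        noisy = np.clip(ideal + rng.normal(0.0, config.sigma, len(times)),
                        0.0, None)
        noisy[0] = max(noisy[0], 1e-3)
        curves.append(DecayCurve(times.copy(), noisy,
                                 replicate_id=f"rep{r + 1}"))
    return curves, truth


@dataclass(frozen=True)
class SyntheticConfig:
    """Bundle of the four generator configs plus the master seed."""

    seed: int = 0
    topology: TopologySimConfig = TopologySimConfig()
    family: FamilySimConfig = FamilySimConfig()
    bundle: BundleSimConfig = BundleSimConfig()
    decay: DecaySimConfig = DecaySimConfig()

    def generate_all(self) -> dict:
        records, topo_truth = gen_topology_table(self.topology, self.seed)
        fam, fam_truth = gen_family_msa(self.family, self.seed)
        bundle, bundle_truth = gen_helix_bundle(self.bundle, self.seed)
        curves, decay_truth = gen_decay_curves(self.decay, self.seed)
        return {
            "topology": (records, topo_truth),
            "family": (fam, fam_truth),
            "bundle": (bundle, bundle_truth),
            "decay": (curves, decay_truth),
        }
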