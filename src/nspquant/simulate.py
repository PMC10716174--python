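"""Synthetic triple-SILAC precursor reports with known ground truth.

The generator emulates the statistical structure of channel-resolved
precursor matrices produced by plexDIA-style searches of pulse-labeled
samples: per-protein baseline abundances and per-peptide ionization
efficiencies are log-normal, channel intensities follow defined mixing
proportions (e.g. the 70/15/15 and 20/40/40 L/M/H benchmark mixtures),
intensities carry multiplicative log-normal noise, rows go missing at a
fixed rate, a fraction of rows receives failing channel/translated
q-values, and "sticky" unlabeled background can contaminate the light
channel independently of protein abundance.

Time-course designs add step-shaped regulation of the treatment channel
from a per-class onset time point onward, so early / intermediate / late
response classes can be planted and recovered downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RegulationSpec",
    "SimDesign",
    "GroundTruth",
    "ConfigError",
    "generate_ground_truth",
    "simulate_precursor_report",
    "write_report",
    "write_ground_truth",
    "write_design",
]

CHANNELS = ("L", "M", "H")

# 20 proteinogenic amino acids, used to mint unique tryptic-looking peptides.
_AA = "ACDEFGHIKLMNPQRSTVWY"


class ConfigError(ValueError):
    """A simulation design violates one of its invariants."""


@dataclass(frozen=True)
class RegulationSpec:
    """One regulation class: which fraction of proteins it covers, the
    signed log2 effect applied to the treatment channel, and the time
    point from which the step change is active."""

    fraction: float
    log2_effect: float
    onset: str
    direction: str = "up"  # "up" or "down"; flips the sign of log2_effect

    @property
    def signed_effect(self) -> float:
        return -abs(self.log2_effect) if self.direction == "down" else abs(self.log2_effect)


@dataclass(frozen=True)
class SimDesign:
    """Parameters of a synthetic triple-SILAC experiment.

    ``channel_proportions`` are the mixing fractions of total protein per
    channel (must sum to 1).  With ``time_points`` empty a single-condition
    benchmark mixture is generated; otherwise each time point is a sample
    measured in ``n_replicates`` runs and ``regulation`` classes modulate
    the treatment channel.
    """

    n_proteins: int = 1000
    peptides_per_protein_mean: float = 5.0
    peptides_per_protein_dispersion: float = 2.0
    channel_proportions: dict = field(
        default_factory=lambda: {"L": 0.70, "M": 0.15, "H": 0.15}
    )
    n_replicates: int = 3
    time_points: tuple = ()
    regulation: dict = field(default_factory=dict)  # class name -> RegulationSpec
    treatment_channel: str = "H"
    control_channel: str = "M"
    noise_sd_log2: float = 0.25
    missing_rate: float = 0.05
    contamination_rate: float = 0.0
    decoy_rate: float = 0.02
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    ionization_log2_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "time_points", tuple(self.time_points))
        reg = {
            k: (v if isinstance(v, RegulationSpec) else RegulationSpec(**v))
            for k, v in self.regulation.items()
        }
        object.__setattr__(self, "regulation", reg)
        self.validate()

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if self.peptides_per_protein_mean < 1:
            raise ConfigError("peptides_per_protein_mean must be >= 1")
        if self.peptides_per_protein_dispersion <= 0:
            raise ConfigError("peptides_per_protein_dispersion must be > 0")
        if set(self.channel_proportions) != set(CHANNELS):
            raise ConfigError(
                f"channel_proportions must map exactly {CHANNELS}, "
                f"got {sorted(self.channel_proportions)}"
            )
        total = sum(self.channel_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"channel_proportions must sum to 1, got {total!r}")
        if any(not (0.0 <= v <= 1.0) for v in self.channel_proportions.values()):
            raise ConfigError("channel_proportions entries must lie in [0, 1]")
        for name in ("missing_rate", "contamination_rate", "decoy_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if self.noise_sd_log2 < 0:
            raise ConfigError("noise_sd_log2 must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.treatment_channel not in CHANNELS or self.control_channel not in CHANNELS:
            raise ConfigError("treatment_channel/control_channel must be one of L/M/H")
        frac = sum(r.fraction for r in self.regulation.values())
        if frac > 1.0 + 1e-9:
            raise ConfigError(f"regulation fractions must sum to <= 1, got {frac!r}")
        for name, r in self.regulation.items():
            if not (0.0 <= r.fraction <= 1.0):
                raise ConfigError(f"regulation[{name}].fraction must lie in [0, 1]")
            if self.time_points and r.onset not in self.time_points:
                raise ConfigError(
                    f"regulation[{name}].onset {r.onset!r} not among time_points "
                    f"{list(self.time_points)}"
                )

    @property
    def samples(self) -> tuple:
        """Sample labels: the time points, or a single benchmark mixture."""
        return self.time_points if self.time_points else ("mix",)

    @property
    def runs(self) -> list:
        """(run label, sample label) pairs, one run per sample x replicate."""
        return [
            (f"{s}_rep{r + 1}", s)
            for s in self.samples
            for r in range(self.n_replicates)
        ]


@dataclass(frozen=True)
class GroundTruth:
    """True quantities behind one synthetic report.

    proteins:  one row per protein — accession, gene, regulation class,
               baseline abundance, sticky L-channel background, and the
               true log2 fold change at every time point.
    peptides:  one row per peptide — protein, sequence, charge,
               multiplicative ionization factor.
    abundance: true channel abundance per (protein, sample, channel),
               before ionization, noise and missingness.
    """

    design: SimDesign
    proteins: pd.DataFrame
    peptides: pd.DataFrame
    abundance: pd.DataFrame


def _rng(design: SimDesign, stream: int) -> np.random.Generator:
    # One design seed governs everything; separate streams per stage keep
    # ground truth stable when only report-level draws are needed again.
    return np.random.default_rng(np.random.SeedSequence(design.seed).spawn(stream + 1)[stream])


def _peptide_sequences(n: int) -> np.ndarray:
    """Deterministic unique tryptic-looking sequences (base-20 index + K)."""
    seqs = np.empty(n, dtype=object)
    for i in range(n):
        x, chars = i, []
        for _ in range(7):
            chars.append(_AA[x % 20])
            x //= 20
        seqs[i] = "".join(reversed(chars)) + "K"
    return seqs


def generate_ground_truth(design: SimDesign) -> GroundTruth:
    """Draw per-protein baselines, regulation classes, peptides and true
    channel abundances for ``design``.  Deterministic given the seed."""
    design.validate()
    rng = _rng(design, 0)
    n = design.n_proteins

    accession = np.array([f"P{i:05d}" for i in range(n)], dtype=object)
    gene = np.array([f"GENE{i}" for i in range(n)], dtype=object)
    baseline = 2.0 ** rng.normal(design.baseline_log2_mean, design.baseline_log2_sd, n)

    classes = list(design.regulation)
    probs = [design.regulation[c].fraction for c in classes]
    classes.append("none")
    probs.append(max(0.0, 1.0 - sum(probs)))
    cls = rng.choice(np.array(classes, dtype=object), size=n, p=np.array(probs) / sum(probs))

    # Step-shaped true log2 FC per time point: the signed effect from the
    # class onset onward, zero before; all-zero for unregulated proteins.
    tps = list(design.samples)
    fc = np.zeros((n, len(tps)))
    for cname, spec in design.regulation.items():
        if not design.time_points:
            continue
        onset_idx = tps.index(spec.onset)
        fc[np.asarray(cls == cname), onset_idx:] = spec.signed_effect

    # Sticky unlabeled background: drawn from the global abundance
    # distribution, independent of the protein's own baseline.
    sticky = rng.random(n) < design.contamination_rate
    sticky_intensity = np.where(
        sticky, 2.0 ** rng.normal(design.baseline_log2_mean, design.baseline_log2_sd, n), 0.0
    )

    proteins = pd.DataFrame(
        {"protein_group": accession, "gene": gene, "regulation_class": cls,
         "baseline": baseline, "sticky_l_intensity": sticky_intensity}
    )
    for j, tp in enumerate(tps):
        proteins[f"true_log2fc_{tp}"] = fc[:, j]

    # Peptides: overdispersed counts (negative binomial, floored at 1).
    r = design.peptides_per_protein_dispersion
    p = r / (r + (design.peptides_per_protein_mean - 1.0)) if design.peptides_per_protein_mean > 1 else 1.0
    npep = 1 + rng.negative_binomial(r, p, n)
    pep_protein = np.repeat(np.arange(n), npep)
    total_pep = int(npep.sum())
    peptides = pd.DataFrame(
        {
            "protein_group": accession[pep_protein],
            "stripped_sequence": _peptide_sequences(total_pep),
            "charge": rng.choice([2, 3], size=total_pep),
            "ionization_factor": 2.0 ** rng.normal(0.0, design.ionization_log2_sd, total_pep),
        }
    )

    # True channel abundance per (protein, sample, channel).
    rows = []
    for j, s in enumerate(tps):
        for ch in CHANNELS:
            a = baseline * design.channel_proportions[ch]
            if ch == design.treatment_channel:
                a = a * 2.0 ** fc[:, j]
            if ch == "L":
                a = a + sticky_intensity
            rows.append(pd.DataFrame(
                {"protein_group": accession, "sample": s, "channel": ch, "abundance": a}
            ))
    abundance = pd.concat(rows, ignore_index=True)

    return GroundTruth(design=design, proteins=proteins, peptides=peptides, abundance=abundance)


def simulate_precursor_report(truth: GroundTruth, design: SimDesign) -> pd.DataFrame:
    """Expand ground truth into a channel-resolved precursor report.

    One row per (peptide, channel, run); MS1- and MS2-style quantities are
    the true channel abundance x ionization factor x independent log-normal
    noise.  Missingness drops rows, a ``decoy_rate`` fraction receives
    failing channel/translated q-values.  Returns a DataFrame in the
    DIA-NN channel-matrix column dialect.
    """
    if truth.design != design:
        raise ValueError("ground truth was generated from a different design")
    rng = _rng(design, 1)

    pep = truth.peptides
    npep = len(pep)
    runs = design.runs
    n_rows = npep * len(CHANNELS) * len(runs)

    # Row order: peptide-major, then channel, then run (stable & explicit).
    pep_idx = np.repeat(np.arange(npep), len(CHANNELS) * len(runs))
    ch_idx = np.tile(np.repeat(np.arange(len(CHANNELS)), len(runs)), npep)
    run_idx = np.tile(np.arange(len(runs)), npep * len(CHANNELS))

    # Dense (protein, sample, channel) cube for fast fancy indexing.
    acc = truth.proteins["protein_group"].to_numpy()
    tps = list(design.samples)
    cube = (
        truth.abundance.pivot_table(
            index="protein_group", columns=["sample", "channel"], values="abundance", sort=False
        )
        .reindex(index=acc, columns=pd.MultiIndex.from_product([tps, list(CHANNELS)]))
        .to_numpy()
        .reshape(len(acc), len(tps), len(CHANNELS))
    )
    prot_of_pep = pd.Index(acc).get_indexer(pep["protein_group"])
    sample_of_run = np.array([tps.index(s) for _, s in runs])

    prot_i = prot_of_pep[pep_idx]
    prot = acc[prot_i]
    sample_i = sample_of_run[run_idx]
    run = np.array([r for r, _ in runs], dtype=object)[run_idx]
    chan = np.array(CHANNELS, dtype=object)[ch_idx]
    true_a = cube[prot_i, sample_i, ch_idx]
    ionf = pep["ionization_factor"].to_numpy()[pep_idx]

    sigma = design.noise_sd_log2
    ms1 = true_a * ionf * 2.0 ** rng.normal(0.0, sigma, n_rows)
    ms2 = true_a * ionf * 2.0 ** rng.normal(0.0, sigma, n_rows)

    keep = rng.random(n_rows) >= design.missing_rate
    decoy = rng.random(n_rows) < design.decoy_rate
    q = rng.uniform(1e-6, 0.009, n_rows)
    chq = np.where(decoy, rng.uniform(0.02, 0.5, n_rows), rng.uniform(1e-6, 0.009, n_rows))
    trq = np.where(decoy, rng.uniform(0.02, 0.5, n_rows), rng.uniform(1e-6, 0.009, n_rows))

    gene_of = truth.proteins.set_index("protein_group")["gene"]
    report = pd.DataFrame(
        {
            "Protein.Group": prot,
            "Genes": gene_of.loc[prot].to_numpy(),
            "Stripped.Sequence": pep["stripped_sequence"].to_numpy()[pep_idx],
            "Modified.Sequence": pep["stripped_sequence"].to_numpy()[pep_idx],
            "Precursor.Charge": pep["charge"].to_numpy()[pep_idx],
            "Channel": chan,
            "Run": run,
            "Ms1.Translated": ms1,
            "Precursor.Translated": ms2,
            "Q.Value": q,
            "Channel.Q.Value": chq,
            "Translated.Q.Value": trq,
        }
    )
    return report.loc[keep].reset_index(drop=True)


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)


def write_ground_truth(truth: GroundTruth, proteins_path, abundance_path=None) -> None:
    truth.proteins.to_csv(proteins_path, sep="\t", index=False)
    if abundance_path is not None:
        truth.abundance.to_csv(abundance_path, sep="\t", index=False)


def write_design(design: SimDesign, path) -> None:
    d = dataclasses.asdict(design)
    d["time_points"] = list(design.time_points)
    d["regulation"] = {k: dataclasses.asdict(v) for k, v in design.regulation.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def design_from_dict(d: dict) -> SimDesign:
    d = dict(d)
    if "regulation" in d:
        d["regulation"] = {
            k: (v if isinstance(v, RegulationSpec) else RegulationSpec(**v))
            for k, v in d["regulation"].items()
        }
    if "time_points" in d and d["time_points"] is not None:
        d["time_points"] = tuple(d["time_points"])
    try:
        return SimDesign(**d)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
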