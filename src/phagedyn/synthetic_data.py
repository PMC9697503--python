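"""Synthetic dual-organism infection time courses with known ground truth.

The generator emulates the dynamics of a lytic dsDNA phage infecting a
bacterial host, as they appear in dual RNA-seq and label-free proteomics
time courses:

* host mRNAs (and most non-coding RNAs) at steady state before infection,
  decaying exponentially after a short delay;
* a small set of highly abundant, stable host non-coding RNAs;
* host tRNAs that rise briefly after infection and then decay;
* phage genes switching on in early/middle/late waves, with a subset of
  early transcripts peaking mid-infection and declining;
* a takeover curve in which the phage's share of the (rRNA-free)
  transcriptome grows monotonically to a configured final fraction;
* a stable host proteome, and phage proteins accumulating after
  class-specific onsets, censored below an LFQ detection limit.

Counts are drawn per sample from a negative-binomial model at a fixed
library size; LFQ intensities get multiplicative log-normal noise.  All
randomness flows from one integer seed through per-table substreams, so
identical configurations produce byte-identical scenario files.

Abundances are constructed in relative (TPM-like) space.  Because TPM is
compositional, the per-gene *measured* trajectory depends on the total
abundance at each time; the generator keeps the rRNA-free total constant
once host decay has begun (mirroring the near-constant total-RNA yields
typical of such experiments), so planted exponential decays re-appear as
the same exponentials in percent-of-baseline TPM curves.  Ground-truth
onset, peak and class labels are computed from the exact noise-free
abundance curves with an independent in-module implementation of the
10%-of-maximum onset rule.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .matrices import (
    AbundanceMatrix,
    CountMatrix,
    Unit,
    ValidationError,
    sample_index,
    validate_annotation,
)
from . import io_formats


def _subseed(seed: int, table: str) -> list[int]:
    return [int(seed) % (2**31), zlib.crc32(table.encode()) % (2**31)]


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of one synthetic infection scenario.

    Defaults describe the reference study conditions: RNA sampled at
    0/1/4/7/20 min and protein at 0/1/3/5/8/12/20/30 min in triplicate,
    host mRNA decay starting after 1 min at 0.2/min, four stable host
    non-coding RNAs, 22 rRNA genes, class proportions heavily weighted
    towards early phage genes, and a final phage transcriptome share of
    0.83.
    """

    seed: int = 0
    time_grid_rna: tuple = (0.0, 1.0, 4.0, 7.0, 20.0)
    time_grid_protein: tuple = (0.0, 1.0, 3.0, 5.0, 8.0, 12.0, 20.0, 30.0)
    n_replicates: int = 3
    n_host_genes: int = 1000
    n_phage_genes: int = 500
    n_stable_host: int = 4
    n_host_trna: int = 60
    n_host_rrna: int = 22
    n_host_ncrna: int = 20
    host_decay_delay_min: float = 1.0
    host_decay_rate_per_min: float = 0.2
    trna_rise_factor: float = 1.3
    phage_class_proportions: tuple = (0.78, 0.08, 0.14)
    early_peak_decline_fraction: float = 0.5
    takeover_final_fraction: float = 0.83
    phage_initial_mass_fraction: float = 0.15
    rrna_mass_fraction: float = 0.005
    library_size: int = 2_000_000
    nb_dispersion: float = 0.1
    count_noise: str = "nb"  # "nb" | "poisson" | "none"
    lfq_log_sd: float = 0.1
    lfq_noise: bool = True
    lfq_detection_limit: float = 2e5
    lfq_final_phage_fraction: float = 0.14
    host_protein_detected_fraction: float = 0.6
    phage_protein_detected_fraction: float = 0.85
    decoupled_fraction: float = 0.30

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        props = np.asarray(self.phage_class_proportions, dtype=float)
        if len(props) != 3 or (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"phage_class_proportions must be a 3-simplex, got {self.phage_class_proportions}"
            )
        for grid_name in ("time_grid_rna", "time_grid_protein"):
            grid = np.asarray(getattr(self, grid_name), dtype=float)
            if grid[0] != 0 or (np.diff(grid) <= 0).any():
                raise ValidationError(f"{grid_name} must be strictly increasing from 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        for name in ("host_decay_rate_per_min", "nb_dispersion", "lfq_log_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in (
            "takeover_final_fraction",
            "lfq_final_phage_fraction",
        ):
            if not (0 < getattr(self, name) < 1):
                raise ValidationError(f"{name} must be in (0, 1)")
        if self.count_noise not in ("nb", "poisson", "none"):
            raise ValidationError(f"unknown count_noise {self.count_noise!r}")
        n_special = self.n_host_rrna + self.n_host_trna + self.n_host_ncrna
        if n_special >= self.n_host_genes:
            raise ValidationError("n_host_genes too small for the special biotypes")
        if self.n_stable_host > self.n_host_ncrna:
            raise ValidationError("n_stable_host cannot exceed n_host_ncrna")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("time_grid_rna", "time_grid_protein", "phage_class_proportions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("time_grid_rna", "time_grid_protein", "phage_class_proportions"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _largest_remainder(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Integer allocation of n items to classes, preserving the simplex."""
    raw = np.asarray(proportions, dtype=float) * n
    base = np.floor(raw).astype(int)
    rest = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rest]] += 1
    return base


def _onset_peak_class(
    curve: np.ndarray,
    times: np.ndarray,
    early_end: float,
    late_start: float,
    onset_fraction: float = 0.10,
) -> tuple[float, float, str]:
    """Independent implementation of the onset rule used for truth labels."""
    peak = curve.max()
    if peak <= 0:
        return (np.nan, np.nan, "unexpressed")
    onset = float(times[int(np.argmax(curve >= onset_fraction * peak))])
    peak_t = float(times[int(np.argmax(curve))])
    if onset < early_end:
        cls = "early"
    elif onset < late_start:
        cls = "middle"
    else:
        cls = "late"
    return (onset, peak_t, cls)


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic host+phage gene annotation with realistic lengths."""
    rng = np.random.default_rng(_subseed(config.seed, "annotation"))
    n_mrna = config.n_host_genes - config.n_host_rrna - config.n_host_trna - config.n_host_ncrna
    biotypes = (
        ["rRNA"] * config.n_host_rrna
        + ["tRNA"] * config.n_host_trna
        + ["ncRNA"] * config.n_host_ncrna
        + ["mRNA"] * n_mrna
    )
    rng.shuffle(biotypes)
    records = []
    for i, biotype in enumerate(biotypes):
        if biotype == "tRNA":
            length = int(rng.integers(70, 96))
        elif biotype == "rRNA":
            length = int(rng.integers(1500, 2950))
        elif biotype == "ncRNA":
            length = int(rng.integers(60, 400))
        else:
            length = int(rng.integers(200, 3001))
        gid = f"EC{i + 1:04d}"
        records.append(
            {"gene_id": gid, "entity": "host", "length_nt": length, "biotype": biotype, "name": gid}
        )
    for i in range(config.n_phage_genes):
        gid = f"T4p{i + 1:04d}"
        records.append(
            {
                "gene_id": gid,
                "entity": "phage",
                "length_nt": int(rng.integers(200, 3001)),
                "biotype": "mRNA",
                "name": gid,
            }
        )
    annotation = pd.DataFrame(records).set_index("gene_id")
    return validate_annotation(annotation)


def annotation_to_gff3(annotation: pd.DataFrame, path: str | Path) -> Path:
    """Write the annotation as a two-seqid GFF3 file (1-based inclusive)."""
    path = Path(path)
    lines = ["##gff-version 3"]
    cursor = {"host": 1, "phage": 1}
    seqid = {"host": "host_chr", "phage": "phage_chr"}
    for gid, row in annotation.iterrows():
        start = cursor[row["entity"]]
        end = start + int(row["length_nt"]) - 1
        cursor[row["entity"]] = end + 51  # 50 nt intergenic gap
        attrs = f"ID={gid};Name={row['name']};gene_biotype={row['biotype']}"
        lines.append(
            "\t".join(
                [seqid[row["entity"]], "phagedyn_sim", "gene", str(start), str(end), ".", "+", ".", attrs]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@dataclasses.dataclass
class TranscriptomeSim:
    """Counts plus ground truth for one simulated RNA-seq time course."""

    counts: CountMatrix
    truth: pd.DataFrame
    mean_tpm: AbundanceMatrix  # exact noise-free expectation, rRNA excluded
    annotation: pd.DataFrame


def _host_abundance_curves(
    config: SimulationConfig, annotation: pd.DataFrame, rng: np.random.Generator, times: np.ndarray
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Host abundance curves (arbitrary units), per-gene decay rates, stable set.

    Stable non-coding RNAs are returned with unit baselines; the caller
    scales them so the configured final takeover fraction is attainable.
    """
    host = annotation[annotation["entity"] == "host"]
    delay, k0 = config.host_decay_delay_min, config.host_decay_rate_per_min
    curves = {}
    decay_rates = {}
    ncrna_ids = list(host.index[host["biotype"] == "ncRNA"])
    stable_ids = list(rng.choice(ncrna_ids, size=config.n_stable_host, replace=False))
    for gid, row in host.iterrows():
        biotype = row["biotype"]
        k = k0 * float(rng.lognormal(0.0, 0.25))
        if gid in stable_ids:
            curves[gid] = np.full_like(times, float(rng.lognormal(0.0, 0.3)), dtype=float)
            decay_rates[gid] = 0.0
        elif biotype == "rRNA":
            # placeholder; rescaled to the configured rRNA mass afterwards
            curves[gid] = np.full_like(times, float(rng.lognormal(0.0, 0.5)), dtype=float)
            decay_rates[gid] = 0.0
        elif biotype == "tRNA":
            base = float(rng.lognormal(np.log(300.0), 0.8))
            rise = config.trna_rise_factor
            curve = np.where(times <= delay, np.where(times > 0, base * rise, base), 0.0)
            post = base * rise * np.exp(-k * (times - delay))
            curves[gid] = np.where(times > delay, post, curve)
            decay_rates[gid] = k
        else:
            base = float(
                rng.lognormal(np.log(100.0), 1.2)
                if biotype == "mRNA"
                else rng.lognormal(np.log(50.0), 1.0)
            )
            curves[gid] = base * np.where(times <= delay, 1.0, np.exp(-k * np.maximum(times - delay, 0.0)))
            decay_rates[gid] = k
    table = pd.DataFrame(curves, index=times).T
    return table, pd.Series(decay_rates), stable_ids


_EARLY_TEMPLATES = {
    # values at (onset, and subsequent grid points); anchored on the default
    # 5-point grid and interpolated for other grids
    "monotone": (0.60, 0.75, 0.90, 1.00),
    "peak_mid": (0.60, 1.00, 0.70, 0.25),
    "peak_late_mid": (0.50, 0.80, 1.00, 0.45),
}


def _phage_shape(
    rng: np.random.Generator, times: np.ndarray, onset: float, template: str
) -> np.ndarray:
    """Relative expression shape: zero before onset, >= 0.5 of max at onset."""
    active = times >= onset
    n_active = int(active.sum())
    if template == "monotone":
        ramp = np.linspace(0.6, 1.0, n_active)
    elif template == "peak_mid":
        # peak at the second active point, then decline
        peak_pos = min(1, n_active - 1)
        ramp = np.concatenate(
            [np.linspace(0.6, 1.0, peak_pos + 1), np.linspace(1.0, 0.25, n_active - peak_pos)[1:]]
        )
    elif template == "peak_late_mid":
        peak_pos = min(2, n_active - 1)
        ramp = np.concatenate(
            [np.linspace(0.5, 1.0, peak_pos + 1), np.linspace(1.0, 0.45, n_active - peak_pos)[1:]]
        )
    else:
        raise ValidationError(f"unknown shape template {template!r}")
    shape = np.zeros_like(times, dtype=float)
    shape[active] = ramp
    jitter = rng.uniform(0.9, 1.1, size=n_active)
    shape[active] *= jitter
    return shape


def generate_transcriptome(
    config: SimulationConfig, annotation: pd.DataFrame | None = None
) -> TranscriptomeSim:
    """Simulate the dual-organism count table and its ground truth."""
    if annotation is None:
        annotation = generate_annotation(config)
    rng = np.random.default_rng(_subseed(config.seed, "transcriptome"))
    times = np.asarray(config.time_grid_rna, dtype=float)
    final = times[-1]

    host_curves, decay_rates, stable_ids = _host_abundance_curves(
        config, annotation, rng, times
    )
    host = annotation[annotation["entity"] == "host"]
    rrna_ids = list(host.index[host["biotype"] == "rRNA"])
    nonstable_ids = [g for g in host.index if g not in set(stable_ids) and g not in set(rrna_ids)]

    w_ns = host_curves.loc[nonstable_ids].sum(axis=0).to_numpy()  # per time
    w_stable_unit = float(host_curves.loc[stable_ids, times[0]].sum())
    f = config.takeover_final_fraction
    beta = ((1 - f) * w_ns[0] - w_ns[-1]) / (f * w_stable_unit)
    if beta <= 0:
        raise ValidationError(
            "takeover_final_fraction unattainable: host decays too little for "
            "the stable-RNA mass to balance"
        )
    host_curves.loc[stable_ids] *= beta
    total0 = w_ns[0] + beta * w_stable_unit  # rRNA-free host total before infection
    host_total = host_curves.loc[nonstable_ids + stable_ids].sum(axis=0).to_numpy()

    # rRNA genes: constant mass, a configured (small) fraction of all reads
    rrna_mass = config.rrna_mass_fraction / (1 - config.rrna_mass_fraction) * total0
    rrna_weights = host_curves.loc[rrna_ids, times[0]].to_numpy()
    host_curves.loc[rrna_ids] = (
        rrna_mass * rrna_weights[:, None] / rrna_weights.sum()
    ) * np.ones_like(times)

    # phage genes: class-structured shapes, then per-time mass calibration
    phage = annotation[annotation["entity"] == "phage"]
    n_phage = len(phage)
    n_per_class = _largest_remainder(n_phage, config.phage_class_proportions)
    planted = np.repeat(["early", "middle", "late"], n_per_class)
    rng.shuffle(planted)

    positive = times[times > 0]
    onset_early = positive[0]
    onset_middle = times[np.searchsorted(times, 4.0)] if 4.0 <= final else positive[-1]
    shapes = np.zeros((n_phage, len(times)))
    onsets_intended = np.zeros(n_phage)
    for i, cls in enumerate(planted):
        if cls == "early":
            onset = onset_early
            if rng.random() < config.early_peak_decline_fraction:
                template = "peak_mid" if rng.random() < 0.5 else "peak_late_mid"
            else:
                template = "monotone"
        elif cls == "middle":
            onset = onset_middle
            template = "monotone"
        else:
            late_times = times[times >= 7.0]
            onset = float(rng.choice(late_times, p=_late_onset_probs(late_times)))
            template = "monotone"
        onsets_intended[i] = onset
        shapes[i] = _phage_shape(rng, times, onset, template)
    magnitudes = rng.lognormal(0.0, 0.8, size=n_phage)
    phage_raw = shapes * magnitudes[:, None]

    # phage mass target: a configured toehold before host decay starts, then
    # exactly the mass the host has lost (constant rRNA-free total)
    target = np.maximum(config.phage_initial_mass_fraction * total0, total0 - host_total)
    target[0] = 0.0
    raw_totals = phage_raw.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(raw_totals > 0, target / np.where(raw_totals > 0, raw_totals, 1.0), 0.0)
    phage_curves = pd.DataFrame(
        phage_raw * scale[None, :], index=phage.index, columns=times
    )

    abundance = pd.concat([host_curves, phage_curves]).loc[annotation.index]
    abundance.columns = times

    # exact noise-free TPM expectation over the rRNA-free gene set
    non_rrna = [g for g in annotation.index if g not in set(rrna_ids)]
    tpm = abundance.loc[non_rrna]
    tpm = tpm / tpm.sum(axis=0) * 1e6
    tpm.columns = pd.Index(times, name="time_min")
    mean_tpm = AbundanceMatrix(tpm, Unit.TPM)

    # ground-truth labels from the exact TPM curves (independent rule copy)
    truth_rows = []
    for gid in annotation.index:
        row = annotation.loc[gid]
        entry = {
            "gene_id": gid,
            "entity": row["entity"],
            "biotype": row["biotype"],
            "stable": gid in set(stable_ids),
            "decay_rate_per_min": decay_rates.get(gid, np.nan),
            "planted_class": np.nan,
            "class": np.nan,
            "onset_min": np.nan,
            "peak_min": np.nan,
        }
        if row["entity"] == "phage":
            i = phage.index.get_loc(gid)
            onset, peak_t, cls = _onset_peak_class(
                tpm.loc[gid].to_numpy(), times, early_end=4.0, late_start=7.0
            )
            entry.update(
                planted_class=planted[i], **{"class": cls}, onset_min=onset, peak_min=peak_t
            )
        truth_rows.append(entry)
    truth = pd.DataFrame(truth_rows).set_index("gene_id")

    # counts: expected read share proportional to abundance x length
    lengths = annotation["length_nt"].astype(float)
    weights = abundance.mul(lengths, axis=0)
    shares = weights / weights.sum(axis=0)
    reps = range(1, config.n_replicates + 1)
    columns = sample_index([(t, r) for t in times for r in reps])
    mean_counts = np.empty((len(annotation), len(columns)))
    for j, (t, _r) in enumerate(columns):
        mean_counts[:, j] = config.library_size * shares[t].to_numpy()
    counts_arr = _draw_counts(rng, mean_counts, config)
    counts = CountMatrix(
        pd.DataFrame(counts_arr, index=annotation.index.copy(), columns=columns),
        lengths=annotation["length_nt"],
    )
    return TranscriptomeSim(counts=counts, truth=truth, mean_tpm=mean_tpm, annotation=annotation)


def _late_onset_probs(late_times: np.ndarray) -> np.ndarray:
    """Late genes mostly switch on at the first late time point."""
    probs = np.full(len(late_times), 0.2 / max(len(late_times) - 1, 1))
    probs[0] = 0.8
    if len(late_times) == 1:
        probs[:] = 1.0
    return probs / probs.sum()


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    if config.count_noise == "none":
        return np.rint(mean).astype(np.int64)
    if config.count_noise == "poisson" or config.nb_dispersion == 0:
        return rng.poisson(mean).astype(np.int64)
    r = 1.0 / config.nb_dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.int64)


@dataclasses.dataclass
class ProteomeSim:
    """LFQ matrix plus ground truth for one simulated proteome time course."""

    lfq: AbundanceMatrix  # indexed by protein_id
    truth: pd.DataFrame  # indexed by gene_id
    id_map: pd.DataFrame  # gene_id <-> protein_id for detected proteins
    mean_lfq: AbundanceMatrix  # noise-free censored expectation
    protein_annotation: pd.DataFrame  # annotation rows re-indexed by protein_id
    proteome_sizes: dict


def generate_proteome(
    config: SimulationConfig, rna: TranscriptomeSim | None = None
) -> ProteomeSim:
    """Simulate the LFQ table, correlated with the transcriptome truth.

    Detected phage proteins inherit their temporal class from the
    realized RNA class, except for a planted *decoupled* subset (fraction
    of the shared cohort, default 0.30) whose transcripts are early but
    whose proteins appear late.  Proteins never detected are drawn
    preferentially from early transcripts.
    """
    if rna is None:
        rna = generate_transcriptome(config)
    annotation = rna.annotation
    rng = np.random.default_rng(_subseed(config.seed, "proteome"))
    times = np.asarray(config.time_grid_protein, dtype=float)
    final = times[-1]

    host_coding = list(
        annotation.index[(annotation["entity"] == "host") & (annotation["biotype"] == "mRNA")]
    )
    phage_all = list(annotation.index[annotation["entity"] == "phage"])
    n_host_det = int(round(config.host_protein_detected_fraction * len(host_coding)))
    host_det = sorted(rng.choice(host_coding, size=n_host_det, replace=False))

    n_phage_det = int(round(config.phage_protein_detected_fraction * len(phage_all)))
    rna_class = rna.truth.loc[phage_all, "class"]
    early_pool = [g for g in phage_all if rna_class[g] == "early"]
    n_undet = len(phage_all) - n_phage_det
    undet = set(
        rng.choice(early_pool, size=min(n_undet, len(early_pool)), replace=False)
    )
    if len(undet) < n_undet:
        rest = [g for g in phage_all if g not in undet]
        undet |= set(rng.choice(rest, size=n_undet - len(undet), replace=False))
    phage_det = [g for g in phage_all if g not in undet]

    # protein classes: planted decoupling plus class-conditional assignment
    n_dec = int(round(config.decoupled_fraction * len(phage_det)))
    early_det = [g for g in phage_det if rna_class[g] == "early"]
    if len(early_det) < n_dec:
        raise ValidationError(
            "decoupled_fraction too large for the available early transcripts"
        )
    decoupled = set(rng.choice(early_det, size=n_dec, replace=False))
    planted_protein_class = {}
    for g in phage_det:
        if g in decoupled:
            planted_protein_class[g] = "late"
        elif rna_class[g] == "early":
            planted_protein_class[g] = "early" if rng.random() < 0.6 else "middle"
        elif rna_class[g] == "middle":
            planted_protein_class[g] = "middle" if rng.random() < 0.5 else "late"
        else:
            planted_protein_class[g] = "late"

    early_times = times[(times > 0) & (times < 5.0)]
    middle_times = times[(times >= 5.0) & (times < 8.0)]
    late_times = times[(times >= 8.0) & (times < final)]
    onset_pool = {
        "early": early_times if len(early_times) else times[times > 0][:1],
        "middle": middle_times if len(middle_times) else times[times > 0][:1],
        "late": late_times if len(late_times) else times[-1:],
    }
    onsets = {g: float(rng.choice(onset_pool[planted_protein_class[g]])) for g in phage_det}

    # mean curves: host constant; phage 0 before onset, then a saturating
    # ramp from 45% of the plateau at onset to the plateau at the last time
    host_means = pd.DataFrame(
        np.outer(rng.lognormal(np.log(5e7), 1.2, size=len(host_det)), np.ones_like(times)),
        index=pd.Index(host_det, name="gene_id"),
        columns=times,
    )
    phage_plateaus = rng.lognormal(np.log(1e7), 1.0, size=len(phage_det))
    phage_means = pd.DataFrame(0.0, index=pd.Index(phage_det, name="gene_id"), columns=times)
    for i, g in enumerate(phage_det):
        onset = onsets[g]
        active = times >= onset
        ramp = 0.45 + 0.55 * (times[active] - onset) / (final - onset) if final > onset else 1.0
        phage_means.loc[g, active] = phage_plateaus[i] * ramp

    # calibrate total phage LFQ share at the last time point
    target = config.lfq_final_phage_fraction
    host_final = float(host_means[final].sum())
    phage_final = float(phage_means[final].sum())
    gamma = target / (1 - target) * host_final / phage_final
    phage_means *= gamma

    means = pd.concat([host_means, phage_means])
    censored = means.where(means >= config.lfq_detection_limit, 0.0)

    # ground truth from the exact censored curves
    truth_rows = []
    for g in phage_det:
        onset, peak_t, cls = _onset_peak_class(
            censored.loc[g].to_numpy(), times, early_end=5.0, late_start=8.0
        )
        truth_rows.append(
            {
                "gene_id": g,
                "planted_protein_class": planted_protein_class[g],
                "protein_class": cls,
                "protein_onset_min": onset,
                "protein_peak_min": peak_t,
                "decoupled": g in decoupled,
            }
        )
    for g in host_det:
        truth_rows.append(
            {
                "gene_id": g,
                "planted_protein_class": np.nan,
                "protein_class": np.nan,
                "protein_onset_min": np.nan,
                "protein_peak_min": np.nan,
                "decoupled": False,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")

    # noisy replicates, censored at the detection limit
    reps = range(1, config.n_replicates + 1)
    columns = sample_index([(t, r) for t in times for r in reps])
    base = np.empty((len(means), len(columns)))
    for j, (t, _r) in enumerate(columns):
        base[:, j] = means[t].to_numpy()
    if config.lfq_noise and config.lfq_log_sd > 0:
        noise = rng.lognormal(0.0, config.lfq_log_sd, size=base.shape)
        values = base * noise
    else:
        values = base
    values = np.where(values >= config.lfq_detection_limit, values, np.nan)

    id_map = pd.DataFrame(
        {"gene_id": list(means.index), "protein_id": [f"{g}.p" for g in means.index]}
    )
    protein_ids = pd.Index(id_map["protein_id"], name="gene_id")
    lfq = AbundanceMatrix(pd.DataFrame(values, index=protein_ids, columns=columns), Unit.LFQ)
    mean_curves = censored.copy()
    mean_curves.index = protein_ids
    mean_curves.columns = pd.Index(times, name="time_min")
    mean_lfq = AbundanceMatrix(mean_curves.where(mean_curves > 0), Unit.LFQ)
    protein_annotation = annotation.loc[id_map["gene_id"]].copy()
    protein_annotation.index = pd.Index(id_map["protein_id"], name="gene_id")
    sizes = {"host": len(host_coding), "phage": len(phage_all)}
    return ProteomeSim(
        lfq=lfq,
        truth=truth,
        id_map=id_map,
        mean_lfq=mean_lfq,
        protein_annotation=protein_annotation,
        proteome_sizes=sizes,
    )


@dataclasses.dataclass
class Scenario:
    """A complete in-memory scenario: both omics layers plus ground truth."""

    config: SimulationConfig
    annotation: pd.DataFrame
    rna: TranscriptomeSim
    protein: ProteomeSim

    @property
    def truth(self) -> pd.DataFrame:
        """Merged per-gene truth table across both layers."""
        merged = self.rna.truth.join(self.protein.truth, how="left")
        id_lookup = self.protein.id_map.set_index("gene_id")["protein_id"]
        merged["protein_id"] = id_lookup.reindex(merged.index)
        return merged


def simulate_scenario(config: SimulationConfig) -> Scenario:
    """Generate annotation, transcriptome and proteome for one config."""
    annotation = generate_annotation(config)
    rna = generate_transcriptome(config, annotation)
    protein = generate_proteome(config, rna)
    return Scenario(config=config, annotation=annotation, rna=rna, protein=protein)


def write_scenario(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a pipeline-ready scenario to disk.

    Produces counts.tsv (featureCounts layout), proteins_lfq.tsv
    (proteinGroups layout, not-detected written as 0), annotation.gff3,
    id_map.tsv and truth.tsv.  Identical configurations produce
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenario = simulate_scenario(config)
    paths = {}
    paths["counts"] = io_formats.write_table(scenario.rna.counts, out_dir / "counts.tsv")
    paths["gff3"] = annotation_to_gff3(scenario.annotation, out_dir / "annotation.gff3")

    lfq = scenario.protein.lfq
    table = lfq.data.fillna(0.0).copy()
    table.columns = [
        "LFQ intensity " + io_formats.format_sample_name(t, int(r)) for t, r in lfq.data.columns
    ]
    table.insert(0, "Protein IDs", table.index)
    table.insert(1, "Reverse", "")
    table.insert(2, "Potential contaminant", "")
    table.to_csv(out_dir / "proteins_lfq.tsv", sep="\t", index=False, float_format="%.12g")
    paths["lfq"] = out_dir / "proteins_lfq.tsv"

    paths["id_map"] = out_dir / "id_map.tsv"
    scenario.protein.id_map.to_csv(paths["id_map"], sep="\t", index=False)
    paths["truth"] = io_formats.write_table(scenario.truth, out_dir / "truth.tsv")
    config.to_yaml(out_dir / "config.yaml")
    paths["config"] = out_dir / "config.yaml"
    return paths
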