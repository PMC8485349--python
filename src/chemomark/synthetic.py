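"""Synthetic label-free proteomics datasets with planted ground truth.

The generator emulates the statistical structure of a SWATH-type
abundance matrix from a longitudinal meat-maturation design: a small
cohort of animals sampled at ordered timepoints, each biological sample
measured in several technical replicates, with log-scale abundances,
biological variance exceeding technical variance, a planted subset of
timepoint-discriminant proteins with controlled fold changes, an
optional gender effect, and phenotype variables (sensory scores, shear
force) linearly tied to chosen proteins.

Abundances follow a log-normal model: effects are additive on the log
scale and exponentiated,

    x[s, p] = exp(base_p + animal_a + timepoint_{p,t} + gender_{p,g}
                  + bio_noise_{bp} + tech_noise_{sp})

Fold changes are planted on biological means; technical replicates
resample only technical noise around their biological sample.  The
ground truth records the exact per-contrast log fold change of every
protein, enabling recovery tests for the downstream selection stages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import AbundanceDataset, ComparisonDesign

__all__ = ["SyntheticSpec", "GroundTruth", "synthesize", "synthesize_phenotypes"]


def _cv_to_sigma(cv: float) -> float:
    # lognormal identity: CV of exp(N(mu, s^2)) = sqrt(exp(s^2) - 1)
    return math.sqrt(math.log1p(cv * cv))


@dataclass
class SyntheticSpec:
    """Design of a synthetic abundance dataset.

    Defaults reproduce the study layout this generator emulates:
    8 animals (4 heifers, 4 bulls) x 3 timepoints x 3 technical
    replicates with one female t12 biological sample discarded,
    giving 69 rows over 137 proteins.

    Parameters
    ----------
    n_discriminant : int
        Number of planted timepoint-affected proteins.  Each planted
        protein changes monotonically across timepoints: its biological
        mean is multiplied by ``planted_fc`` (or divided, for the
        down-regulated half) at each successive timepoint after the
        first, so every pairwise contrast sees a controlled fold change.
    planted_fc : float or sequence of float
        Multiplicative fold change per timepoint step for planted
        proteins (scalar broadcast, or one value per planted protein).
    biological_cv, technical_cv : float
        Coefficients of variation of the biological and technical
        noise on the natural scale; technical must be < biological.
    animal_cv : float
        Coefficient of variation of the per-animal random offset.
    gender_affected : mapping protein index -> fold change
        Proteins whose biological mean is multiplied by the given fold
        change in females (heifers) relative to males.
    phenotype_links : sequence of (name, protein index, target r)
        Phenotype variables generated per biological sample with the
        requested Pearson correlation to the protein's biological
        log abundance.
    discarded_samples : sequence of (animal_id, timepoint)
        Biological samples removed (all their technical replicates).
    """

    n_animals: int = 8
    genders: Sequence[str] | None = None
    timepoints: Sequence[str] = ("t0", "t12", "t26")
    n_tech_reps: int = 3
    n_proteins: int = 137
    n_discriminant: int = 20
    planted_fc: float | Sequence[float] = 1.8
    biological_cv: float = 0.30
    technical_cv: float = 0.10
    animal_cv: float = 0.10
    baseline_log_mean: float = 9.0
    baseline_log_sd: float = 1.2
    gender_affected: Mapping[int, float] | None = None
    phenotype_links: Sequence[tuple[str, int, float]] = ()
    discarded_samples: Sequence[tuple[str, str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.genders is None:
            half = self.n_animals // 2
            self.genders = ("F",) * half + ("M",) * (self.n_animals - half)
        if len(self.genders) != self.n_animals:
            raise ValueError(
                f"genders has {len(self.genders)} entries for n_animals={self.n_animals}"
            )
        if len(set(self.timepoints)) != len(self.timepoints) or not self.timepoints:
            raise ValueError("timepoints must be nonempty and unique")
        if self.n_tech_reps < 1:
            raise ValueError("n_tech_reps must be >= 1")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0 <= self.n_discriminant <= self.n_proteins:
            raise ValueError("n_discriminant must be in [0, n_proteins]")
        fc = np.atleast_1d(np.asarray(self.planted_fc, dtype=float))
        if not np.all(np.isfinite(fc)) or np.any(fc <= 0):
            raise ValueError("planted_fc entries must be finite and positive")
        if fc.size not in (1, max(self.n_discriminant, 1)):
            raise ValueError(
                "planted_fc must be scalar or have one entry per discriminant protein"
            )
        if not (self.biological_cv >= 0 and self.technical_cv >= 0):
            raise ValueError("biological_cv and technical_cv must be >= 0")
        if self.technical_cv > self.biological_cv:
            raise ValueError("technical_cv must not exceed biological_cv")
        if self.gender_affected:
            for p, g_fc in self.gender_affected.items():
                if not 0 <= p < self.n_proteins:
                    raise ValueError(f"gender_affected protein index {p} out of range")
                if not (np.isfinite(g_fc) and g_fc > 0):
                    raise ValueError(f"gender_affected fold change for protein {p} invalid")
        seen: set[int] = set()
        for name, p, r in self.phenotype_links:
            if not 0 <= p < self.n_proteins:
                raise ValueError(f"phenotype_links protein index {p} out of range")
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"phenotype_links target r for {name!r} outside [-1, 1]")
        if self.discarded_samples is None:
            # mirror the emulated design: one female t12 biological sample dropped
            if len(self.timepoints) >= 2 and "F" in self.genders:
                fem = self.genders.index("F")
                self.discarded_samples = ((f"A{fem + 1}", self.timepoints[1]),)
            else:
                self.discarded_samples = ()

    @property
    def animal_ids(self) -> list[str]:
        return [f"A{i + 1}" for i in range(self.n_animals)]

    def planted_fc_array(self) -> np.ndarray:
        return np.broadcast_to(
            np.atleast_1d(np.asarray(self.planted_fc, dtype=float)),
            (self.n_discriminant,),
        ).astype(float)

    def to_json(self) -> str:
        d = {
            k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
            for k, v in self.__dict__.items()
        }
        d["phenotype_links"] = [list(t) for t in self.phenotype_links]
        d["discarded_samples"] = [list(t) for t in self.discarded_samples]
        if self.gender_affected:
            d["gender_affected"] = {str(k): v for k, v in self.gender_affected.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        if d.get("gender_affected"):
            d["gender_affected"] = {int(k): v for k, v in d["gender_affected"].items()}
        d["phenotype_links"] = tuple(tuple(t) for t in d.get("phenotype_links", []))
        d["discarded_samples"] = tuple(tuple(t) for t in d.get("discarded_samples", []))
        for key in ("genders", "timepoints"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """What was actually planted, for recovery testing.

    ``log_fc`` holds the true per-protein log fold change (natural log,
    class_b over class_a) for every pairwise timepoint contrast and for
    the first-vs-rest contrast; ``discriminant`` maps each contrast to
    the set of proteins with a nonzero true log fold change.
    """

    log_fc: pd.DataFrame
    discriminant: dict[str, set[str]]
    phenotype_r: dict[str, tuple[str, float]]
    timepoint_log_effect: np.ndarray  # proteins x timepoints, log scale

    def true_fc(self, contrast: str) -> pd.Series:
        return np.exp(self.log_fc[contrast])

    def write_tsv(self, path) -> None:
        out = self.log_fc.copy()
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t")


def _contrast_names(timepoints: Sequence[str]) -> list[tuple[str, list[int], list[int]]]:
    tp = list(timepoints)
    out = []
    for i in range(len(tp)):
        for j in range(i + 1, len(tp)):
            out.append((f"{tp[i]}_vs_{tp[j]}", [i], [j]))
    if len(tp) > 2:
        out.append((f"{tp[0]}_vs_rest", [0], list(range(1, len(tp)))))
    return out


def synthesize(spec: SyntheticSpec) -> tuple[AbundanceDataset, GroundTruth]:
    """Generate an abundance dataset and its ground truth from a spec.

    Identical spec and seed give bit-identical output.  One row is
    produced per surviving technical replicate.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_struct, ss_noise, _ = root.spawn(3)
    rng = np.random.default_rng(ss_struct)

    P = spec.n_proteins
    T = len(spec.timepoints)
    animals = spec.animal_ids

    base = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=P)

    # planted timepoint effects (log scale), monotone across timepoints
    tp_effect = np.zeros((P, T))
    planted_idx = np.array([], dtype=int)
    if spec.n_discriminant:
        planted_idx = np.sort(
            rng.choice(P, size=spec.n_discriminant, replace=False)
        )
        fc = spec.planted_fc_array()
        direction = np.where(np.arange(spec.n_discriminant) % 2 == 0, 1.0, -1.0)
        step = direction * np.log(fc)
        for k in range(1, T):
            tp_effect[planted_idx, k] = k * step

    gender_effect = np.zeros(P)  # applied to females, log scale
    if spec.gender_affected:
        for p, g_fc in spec.gender_affected.items():
            gender_effect[p] = math.log(g_fc)

    s_animal = _cv_to_sigma(spec.animal_cv)
    s_bio = _cv_to_sigma(spec.biological_cv)
    s_tech = _cv_to_sigma(spec.technical_cv)

    nrng = np.random.default_rng(ss_noise)
    animal_offset = nrng.normal(0.0, s_animal, size=spec.n_animals) if s_animal else np.zeros(
        spec.n_animals
    )

    discarded = set(map(tuple, spec.discarded_samples))
    sample_ids, rows, meta_rows = [], [], []
    bio_log = {}  # (animal, timepoint) -> biological log-abundance vector
    for a_i, animal in enumerate(animals):
        for t_i, tp in enumerate(spec.timepoints):
            bio_noise = nrng.normal(0.0, s_bio, size=P) if s_bio else np.zeros(P)
            log_mean = (
                base
                + animal_offset[a_i]
                + tp_effect[:, t_i]
                + (gender_effect if spec.genders[a_i] == "F" else 0.0)
                + bio_noise
            )
            tech = (
                nrng.normal(0.0, s_tech, size=(spec.n_tech_reps, P))
                if s_tech
                else np.zeros((spec.n_tech_reps, P))
            )
            if (animal, tp) in discarded:
                continue  # noise already drawn: discards do not reshuffle the rest
            bio_log[(animal, tp)] = log_mean
            for r in range(spec.n_tech_reps):
                sample_ids.append(f"{animal}_{tp}_r{r + 1}")
                rows.append(np.exp(log_mean + tech[r]))
                meta_rows.append(
                    {
                        "animal_id": animal,
                        "gender": spec.genders[a_i],
                        "timepoint": tp,
                        "tech_rep": r + 1,
                    }
                )

    protein_ids = [f"P{i + 1:03d}" for i in range(P)]
    dataset = AbundanceDataset(
        sample_ids=sample_ids,
        metadata=pd.DataFrame(meta_rows, index=sample_ids),
        protein_ids=protein_ids,
        values=np.vstack(rows) if rows else np.empty((0, P)),
    )
    dataset.biological_log_means = bio_log  # used by synthesize_phenotypes

    contrasts = _contrast_names(spec.timepoints)
    log_fc = pd.DataFrame(
        {
            name: tp_effect[:, b].mean(axis=1) - tp_effect[:, a].mean(axis=1)
            for name, a, b in contrasts
        },
        index=protein_ids,
    )
    discriminant = {
        name: {protein_ids[i] for i in np.flatnonzero(np.abs(log_fc[name].to_numpy()) > 0)}
        for name, _, _ in contrasts
    }
    truth = GroundTruth(
        log_fc=log_fc,
        discriminant=discriminant,
        phenotype_r={name: (protein_ids[p], r) for name, p, r in spec.phenotype_links},
        timepoint_log_effect=tp_effect,
    )
    return dataset, truth


def synthesize_phenotypes(dataset: AbundanceDataset, spec: SyntheticSpec) -> pd.DataFrame:
    """Generate phenotype variables per biological sample.

    Each linked phenotype is built as ``r * z + sqrt(1 - r^2) * noise``
    where ``z`` is the standardized biological-sample mean log abundance
    of the linked protein, so the achieved Pearson correlation
    approaches the target ``r`` at large n (technical noise slightly
    attenuates it when correlating against replicate-level data).
    """
    if not spec.phenotype_links:
        return pd.DataFrame()
    protein_pos = {p: i for i, p in enumerate(dataset.protein_ids)}
    root = np.random.SeedSequence(spec.seed)
    _, _, ss_phen = root.spawn(3)
    rng = np.random.default_rng(ss_phen)

    bio = (
        np.log(dataset.to_frame())
        .groupby(
            [dataset.metadata["animal_id"], dataset.metadata["timepoint"]],
            sort=True,
        )
        .mean()
    )
    n = len(bio)
    out = {}
    for name, p_idx, r in spec.phenotype_links:
        pid = f"P{p_idx + 1:03d}"
        if pid not in protein_pos:
            raise ValueError(f"phenotype link references unknown protein {pid!r}")
        x = bio.iloc[:, protein_pos[pid]].to_numpy()
        sd = x.std(ddof=1)
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        noise = rng.standard_normal(n)
        if abs(r) < 1.0:
            # orthogonalize the noise against z so the target r is hit in
            # expectation without being biased by chance correlation
            if sd > 0 and n > 2:
                noise = noise - (noise @ z) / (z @ z) * z
            nsd = noise.std(ddof=1)
            if nsd > 0:
                noise = (noise - noise.mean()) / nsd
        out[name] = r * z + math.sqrt(max(0.0, 1.0 - r * r)) * noise
    index = pd.Index(
        ["_".join(k) for k in bio.index], name="biological_sample"
    )
    return pd.DataFrame(out, index=index)
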