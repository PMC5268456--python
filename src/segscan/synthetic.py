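"""Synthetic expression studies with planted ground truth.

The generator emulates a multi-organ bulk RNA-seq design — organs x ages x
sexes x replicates, 352 samples by default, or the 320-sample layout with
one male-only and one female-only organ — at the level the analysis
consumes: a non-negative FPKM-like matrix. Four transcript classes are
planted:

* stable genes: log-uniform baselines with multiplicative log-normal noise
  clipped so the full max/min range stays within ``stable_fc_max``;
* variable genes: the same noise plus an organ- or age-driven mean shift
  large enough that the trimmed fold change exceeds ``variable_fc_min``;
* unannotated transcripts (empty gene_id), removed by preprocessing;
* redundant transcripts: scaled-down copies of an existing gene's row that
  share its gene_id, removed by mean-based redundancy resolution.

Rare extreme outliers (single cells multiplied or divided by ~1e6) and
zero-inflation of low cells are injected afterwards at recorded positions,
emulating the technical artifacts that motivate trimming. Everything is a
pure function of (design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix_io import ExpressionMatrix, GeneSet, GeneSetCollection, GeneTable

__all__ = [
    "SyntheticDesign",
    "SyntheticTruth",
    "ValidationEffect",
    "generate",
    "generate_gene_sets",
    "generate_validation_tables",
]

ORGANS = (
    "adrenal", "brain", "heart", "kidney", "liver", "lung",
    "muscle", "spleen", "thymus", "testis", "uterus",
)
AGES = ("2wk", "6wk", "21wk", "104wk")
SEXES = ("male", "female")

# safety margin keeping realized stable-gene ranges strictly inside the
# planted bound despite finite sampling
_CLIP_MARGIN = 0.96


@dataclass(frozen=True)
class SyntheticDesign:
    """Generative parameters of a simulated expression study.

    The default design is 11 organs x 4 ages x 2 sexes x 4 replicates =
    352 samples; ``sex_specific_organs=True`` makes the last two organs
    sex-exclusive (testis male-only, uterus female-only), reproducing a
    320-sample layout.
    """

    n_organs: int = 11
    n_ages: int = 4
    n_sexes: int = 2
    n_replicates: int = 4
    n_stable_genes: int = 100
    n_variable_genes: int = 4600
    n_unannotated: int = 150
    n_redundant_extra: int = 150
    stable_fc_max: float = 3.0
    variable_fc_min: float = 10.0
    outlier_rate: float = 0.01
    outlier_factor: float = 1e6
    zero_rate: float = 0.01
    sex_specific_organs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stable_fc_max <= 1.0 / _CLIP_MARGIN:
            raise ValueError(
                "stable_fc_max too close to 1; no noise band fits inside it"
            )
        if self.stable_fc_max >= self.variable_fc_min:
            raise ValueError("stable_fc_max must be below variable_fc_min")
        for name in ("n_organs", "n_ages", "n_sexes", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.sex_specific_organs and (self.n_organs < 3 or self.n_sexes != 2):
            raise ValueError(
                "sex-specific organs need at least 3 organs and exactly 2 sexes"
            )
        for name in ("outlier_rate", "zero_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")
        if self.outlier_factor <= 1:
            raise ValueError("outlier_factor must exceed 1")

    @property
    def n_samples(self) -> int:
        full = self.n_organs * self.n_ages * self.n_sexes * self.n_replicates
        if self.sex_specific_organs:
            # two organs lose one sex each
            return full - 2 * self.n_ages * (self.n_sexes - 1) * self.n_replicates
        return full

    @property
    def n_transcripts(self) -> int:
        return (
            self.n_stable_genes
            + self.n_variable_genes
            + self.n_unannotated
            + self.n_redundant_extra
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth: transcript classes, realized trimmed fold
    changes on the clean (pre-outlier, pre-zero) matrix, and the injected
    outlier positions."""

    transcript_class: dict[str, str]
    gene_class: dict[str, str]
    true_fc: dict[str, float]
    outliers: tuple[tuple[str, str], ...]

    def genes_in_class(self, class_label: str) -> frozenset[str]:
        return frozenset(
            g for g, label in self.gene_class.items() if label == class_label
        )

    @property
    def stable_genes(self) -> frozenset[str]:
        return self.genes_in_class("stable")

    @property
    def variable_genes(self) -> frozenset[str]:
        return self.genes_in_class("variable")


def _sample_frame(design: SyntheticDesign) -> pd.DataFrame:
    organs = [
        ORGANS[i] if i < len(ORGANS) else f"organ{i + 1:02d}"
        for i in range(design.n_organs)
    ]
    ages = [
        AGES[i] if i < len(AGES) else f"age{i + 1:02d}" for i in range(design.n_ages)
    ]
    sexes = [
        SEXES[i] if i < len(SEXES) else f"sex{i + 1}" for i in range(design.n_sexes)
    ]
    male_only = organs[-2] if design.sex_specific_organs else None
    female_only = organs[-1] if design.sex_specific_organs else None
    rows = []
    for organ in organs:
        for age in ages:
            for sex in sexes:
                if organ == male_only and sex != "male":
                    continue
                if organ == female_only and sex != "female":
                    continue
                for rep in range(1, design.n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{organ}_{age}_{sex}_r{rep}",
                            "organ": organ,
                            "age": age,
                            "sex": sex,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows)


def _clipped_noise(
    rng: np.random.Generator, shape: tuple[int, int], half_width: float
) -> np.ndarray:
    """Multiplicative log-noise clipped to +/- half_width so the realized
    max/min ratio of a row can never exceed exp(2 * half_width)."""
    return np.clip(rng.normal(0.0, half_width / 2.0, size=shape), -half_width, half_width)


def generate(
    design: SyntheticDesign, seed: int | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame, GeneTable, SyntheticTruth]:
    """Simulate one expression study.

    Returns the transcript-by-sample matrix (with outliers and zeros
    injected), the sample metadata sheet, the transcript-to-gene table, and
    the planted truth. Deterministic given (design, seed); ``seed`` falls
    back to ``design.seed``.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    meta = _sample_frame(design)
    n_samples = len(meta)
    assert n_samples == design.n_samples

    half = 0.5 * np.log(design.stable_fc_max * _CLIP_MARGIN)

    # --- stable genes -----------------------------------------------------
    n_stable = design.n_stable_genes
    stable_base = 10 ** rng.uniform(-1, 4, size=n_stable)
    stable = stable_base[:, None] * np.exp(
        _clipped_noise(rng, (n_stable, n_samples), half)
    )

    # --- variable genes: organ- or age-driven shifts ----------------------
    n_var = design.n_variable_genes
    var_base = 10 ** rng.uniform(-1, 4, size=n_var)
    variable = var_base[:, None] * np.exp(
        _clipped_noise(rng, (n_var, n_samples), half)
    )
    organ_codes = meta["organ"].to_numpy()
    age_codes = meta["age"].to_numpy()
    organ_levels = list(dict.fromkeys(organ_codes))
    age_levels = list(dict.fromkeys(age_codes))
    # shift factor large enough that trimmed FC >= variable_fc_min even if
    # noise pulls shifted and unshifted cells toward each other
    shift_floor = design.variable_fc_min * design.stable_fc_max
    shifts = shift_floor * 10 ** rng.uniform(0, 2, size=n_var)
    drive_by_organ = rng.random(n_var) < 0.5
    driver_organ = rng.integers(0, len(organ_levels), size=n_var)
    driver_age = rng.integers(0, len(age_levels), size=n_var)
    for i in range(n_var):
        if drive_by_organ[i]:
            mask = organ_codes == organ_levels[driver_organ[i]]
        else:
            mask = age_codes == age_levels[driver_age[i]]
        variable[i, mask] *= shifts[i]

    # --- unannotated transcripts (variable-like expression) ---------------
    n_unann = design.n_unannotated
    unann_base = 10 ** rng.uniform(-1, 4, size=n_unann)
    unann = unann_base[:, None] * np.exp(
        _clipped_noise(rng, (n_unann, n_samples), half)
    )
    if n_unann:
        unann_shifts = shift_floor * 10 ** rng.uniform(0, 2, size=n_unann)
        unann_organ = rng.integers(0, len(organ_levels), size=n_unann)
        for i in range(n_unann):
            unann[i, organ_codes == organ_levels[unann_organ[i]]] *= unann_shifts[i]

    # --- assemble primary transcripts, shuffled ---------------------------
    classes = (
        ["stable"] * n_stable + ["variable"] * n_var + ["unannotated"] * n_unann
    )
    values = np.vstack([stable, variable, unann]) if classes else np.empty((0, n_samples))
    order = rng.permutation(len(classes))
    values = values[order]
    classes = [classes[i] for i in order]

    transcript_ids = [f"T{i + 1:05d}" for i in range(len(classes))]
    gene_ids = []
    gene_counter = 0
    for cls in classes:
        if cls == "unannotated":
            gene_ids.append("")
        else:
            gene_counter += 1
            gene_ids.append(f"G{gene_counter:05d}")

    # --- redundant duplicates: lower-mean copies of annotated rows --------
    annotated_rows = [i for i, g in enumerate(gene_ids) if g]
    n_extra = design.n_redundant_extra
    if n_extra:
        if n_extra > len(annotated_rows):
            raise ValueError("more redundant duplicates requested than annotated rows")
        dup_targets = rng.choice(annotated_rows, size=n_extra, replace=False)
        dup_scale = rng.uniform(0.1, 0.8, size=n_extra)
        dup_values = values[dup_targets] * dup_scale[:, None]
        for target in dup_targets:
            transcript_ids.append(f"T{len(transcript_ids) + 1:05d}")
            gene_ids.append(gene_ids[target])
            classes.append("redundant-duplicate")
        values = np.vstack([values, dup_values])

    # --- realized trimmed fold changes on the clean matrix ----------------
    n_rows = values.shape[0]
    ordered = np.sort(values, axis=1)
    clean_fc = ordered[:, -2] / ordered[:, 1]  # trim_k = 1
    for i in range(n_rows):
        if classes[i] == "stable" and clean_fc[i] > design.stable_fc_max:
            raise RuntimeError(
                f"planted stable transcript {transcript_ids[i]} violates its "
                f"fold-change bound ({clean_fc[i]:.3f} > {design.stable_fc_max})"
            )
        if classes[i] == "variable" and clean_fc[i] < design.variable_fc_min:
            raise RuntimeError(
                f"planted variable transcript {transcript_ids[i]} falls below "
                f"its fold-change floor ({clean_fc[i]:.3f} < {design.variable_fc_min})"
            )

    # --- inject outliers at recorded positions ----------------------------
    sample_ids = meta["sample_id"].tolist()
    outliers: list[tuple[str, str]] = []
    hit = rng.random(n_rows) < design.outlier_rate
    out_col = rng.integers(0, n_samples, size=n_rows)
    out_up = rng.random(n_rows) < 0.5
    for i in range(n_rows):
        if not hit[i]:
            continue
        j = int(out_col[i])
        if out_up[i]:
            values[i, j] *= design.outlier_factor
        else:
            values[i, j] /= design.outlier_factor
        outliers.append((transcript_ids[i], sample_ids[j]))

    # --- zero-inflate low cells of non-stable transcripts ------------------
    # (stable rows are exempt: zero substitution would re-insert values
    # outside their clipped noise band and void the planted bound)
    if design.zero_rate > 0:
        for i in range(n_rows):
            if classes[i] == "stable":
                continue
            low_cells = np.argsort(values[i])[:2]
            zero_mask = rng.random(low_cells.size) < design.zero_rate
            values[i, low_cells[zero_mask]] = 0.0

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=transcript_ids, columns=sample_ids)
    )
    gene_table = GeneTable(dict(zip(transcript_ids, gene_ids)))

    gene_class: dict[str, str] = {}
    for tid, gid, cls in zip(transcript_ids, gene_ids, classes):
        if gid and cls != "redundant-duplicate":
            gene_class[gid] = cls
    truth = SyntheticTruth(
        transcript_class=dict(zip(transcript_ids, classes)),
        gene_class=gene_class,
        true_fc=dict(zip(transcript_ids, clean_fc.tolist())),
        outliers=tuple(outliers),
    )
    return matrix, meta, gene_table, truth


def generate_gene_sets(
    truth: SyntheticTruth,
    n_sets: int,
    planted_set_from: str | None = "stable",
    seed: int = 0,
    set_size: int = 30,
    planted_purity: float = 0.9,
) -> GeneSetCollection:
    """Gene-set collection with one optional planted set drawn mostly from a
    given truth class plus uniformly random filler sets.

    With ``planted_set_from=None`` every set is a random (null) set. The
    planted set is named ``planted_<class>`` and its composition is noted in
    the set description.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be at least 1")
    rng = np.random.default_rng(seed)
    all_genes = sorted(truth.gene_class)
    collection = GeneSetCollection()
    n_random = n_sets
    if planted_set_from is not None:
        pool = sorted(truth.genes_in_class(planted_set_from))
        if not pool:
            raise ValueError(f"truth has no genes of class {planted_set_from!r}")
        n_from_class = min(len(pool), int(round(planted_purity * set_size)))
        members = list(rng.choice(pool, size=n_from_class, replace=False))
        others = [g for g in all_genes if g not in set(members)]
        n_fill = min(len(others), set_size - n_from_class)
        if n_fill > 0:
            members += list(rng.choice(others, size=n_fill, replace=False))
        collection.add(
            GeneSet(
                name=f"planted_{planted_set_from}",
                description=(
                    f"planted: {n_from_class} {planted_set_from} genes + "
                    f"{len(members) - n_from_class} random"
                ),
                members=tuple(members),
            )
        )
        n_random -= 1
    for k in range(n_random):
        members = rng.choice(all_genes, size=min(set_size, len(all_genes)), replace=False)
        collection.add(
            GeneSet(
                name=f"random_{k + 1:03d}",
                description="uniform random set",
                members=tuple(members),
            )
        )
    return collection


@dataclass(frozen=True)
class ValidationEffect:
    """Effect sizes for the downstream validation tables.

    ``lethal_odds`` is the planted odds ratio of lethal knockout for
    stable-gene homologs against the ``lethal_rate_other`` baseline;
    ``score_shift`` is the additive shift of stable-homolog scores on a
    damage-index-like scale (negative = less damage).
    """

    homolog_coverage: float = 0.8
    lethal_rate_other: float = 0.31
    lethal_odds: float = 30.0
    score_mean: float = 4.35
    score_sd: float = 2.0
    score_shift: float = -1.1

    def __post_init__(self) -> None:
        if not 0 <= self.homolog_coverage <= 1:
            raise ValueError("homolog_coverage must be a probability")
        if not 0 < self.lethal_rate_other < 1:
            raise ValueError("lethal_rate_other must be in (0, 1)")
        if self.lethal_odds <= 0:
            raise ValueError("lethal_odds must be positive")
        if self.score_sd <= 0:
            raise ValueError("score_sd must be positive")

    @property
    def lethal_rate_stable(self) -> float:
        base_odds = self.lethal_rate_other / (1 - self.lethal_rate_other)
        odds = self.lethal_odds * base_odds
        return odds / (1 + odds)


def generate_validation_tables(
    truth: SyntheticTruth,
    effect: ValidationEffect = ValidationEffect(),
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, bool], dict[str, float]]:
    """Homolog map, binary lethality table, and scalar score table with
    planted group effects for the stable class.

    Homologs are named ``HS_<gene>``; lethality flags are Bernoulli with a
    higher rate for stable-gene homologs, and scores are normal with a
    shifted mean for stable-gene homologs (floored at 0.01 to stay on a
    damage-index-like non-negative scale).
    """
    rng = np.random.default_rng(seed)
    genes = sorted(truth.gene_class)
    homolog_map: dict[str, str] = {}
    for gene in genes:
        if rng.random() < effect.homolog_coverage:
            homolog_map[gene] = f"HS_{gene}"
    lethality: dict[str, bool] = {}
    scores: dict[str, float] = {}
    for gene, homolog in homolog_map.items():
        is_stable = truth.gene_class[gene] == "stable"
        rate = effect.lethal_rate_stable if is_stable else effect.lethal_rate_other
        lethality[homolog] = bool(rng.random() < rate)
        mean = effect.score_mean + (effect.score_shift if is_stable else 0.0)
        scores[homolog] = float(max(0.01, rng.normal(mean, effect.score_sd)))
    return homolog_map, lethality, scores
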