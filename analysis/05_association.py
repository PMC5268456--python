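#!/usr/bin/env python
"""Downstream validation of the SEG list.

Three analyses: (1) the knockout-lethality 2x2 association computed from
the published mouse-knockout counts (15/16 SEG-homolog knockouts lethal
vs 421/1341 others); (2) the same association on synthetic lethality
tables with a planted odds ratio; (3) Mann-Whitney rank comparisons
showing SEG homologs have lower planted damage-index scores. Writes all
statistics to results/05_association.json.
"""

from __future__ import annotations

import argparse
import dataclasses
import importlib.util
import json
import math
from pathlib import Path

import segscan as sg

ROOT = Path(__file__).resolve().parents[1]
_spec = importlib.util.spec_from_file_location(
    "preprocess_step", ROOT / "analysis" / "02_preprocess.py"
)
_preprocess = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_preprocess)

# published mouse-knockout phenotype counts (SEG homologs lethal/non-lethal,
# other genes lethal/non-lethal)
KNOCKOUT_COUNTS = (15, 1, 421, 920)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    published = sg.two_by_two(sg.ContingencyTable(*KNOCKOUT_COUNTS))
    print("published knockout-lethality table "
          f"{KNOCKOUT_COUNTS}: OR={published.odds_ratio:.2f} "
          f"(95% CI {published.ci_low:.2f}-{published.ci_high:.2f}), "
          f"p={published.p_value:.3g}")
    print(f"  lethal fraction: SEG homologs {100 * published.prop1:.0f}%, "
          f"others {100 * published.prop2:.0f}%")

    _, clean, _, truth = _preprocess.preprocessed_study(args.seed)
    segs = sg.seg_gene_set(clean, 4.0, 1)
    effect = sg.ValidationEffect()
    homologs, lethality, scores = sg.generate_validation_tables(
        truth, effect, seed=args.seed + 21
    )
    mapped = sg.map_homologs(segs, homologs)
    print(f"{len(mapped.mapped)} of {mapped.n_input} SEGs have homologs "
          f"({mapped.n_unmapped} unmapped)")

    table = sg.lethality_table(mapped.mapped, lethality)
    synth = sg.two_by_two(table)
    print(f"synthetic lethality table ({table.n_a}, {table.n_b}, {table.n_c}, "
          f"{table.n_d}): OR={synth.odds_ratio:.1f} "
          f"(planted {effect.lethal_odds}), p={synth.p_value:.3g}")

    group = set(mapped.mapped) & scores.keys()
    rank = sg.rank_compare(scores, group, alternative="group-lower")
    print(f"damage-score rank test (group-lower): U={rank.u_statistic:.0f}, "
          f"p={rank.p_value:.3g}; medians {rank.median_group:.2f} vs "
          f"{rank.median_rest:.2f}")

    out = ROOT / "results" / "05_association.json"
    out.parent.mkdir(exist_ok=True)
    with open(out, "w", encoding="utf-8") as handle:
        json.dump(
            {
                "seed": args.seed,
                "published_knockout": {
                    "counts": list(KNOCKOUT_COUNTS),
                    "odds_ratio": published.odds_ratio,
                    "ci": [published.ci_low, published.ci_high],
                    "p_value": published.p_value,
                    "prop_seg_lethal": published.prop1,
                    "prop_other_lethal": published.prop2,
                },
                "synthetic_knockout": {
                    "counts": [table.n_a, table.n_b, table.n_c, table.n_d],
                    "odds_ratio": None
                    if math.isinf(synth.odds_ratio) else synth.odds_ratio,
                    "planted_odds": effect.lethal_odds,
                    "p_value": synth.p_value,
                },
                "damage_score_rank_test": dataclasses.asdict(rank),
            },
            handle,
            indent=2,
        )
    print(f"statistics written to {out}")


if __name__ == "__main__":
    main()
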