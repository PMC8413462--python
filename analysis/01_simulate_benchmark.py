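#!/usr/bin/env python
"""Generate the labelled synthetic snoRNA benchmark.

Writes a balanced benchmark (200 records per category, seed 101) plus a
yeast-census-proportioned cohort of 43 records (the default category mix)
under results/benchmark/.  Every downstream analysis step reads these
files; the truth tables carry the planted box coordinates (1-based) and
categories.
"""

from pathlib import Path

from snokturn.functional_classification import Category
from snokturn.synthetic_data import GenerationSpec, generate_snorna, write_benchmark

RESULTS = Path(__file__).resolve().parents[1] / "results" / "benchmark"


def main() -> None:
    balanced = generate_snorna(
        GenerationSpec(seed=101, n=1000, category_mix={c: 0.2 for c in Category})
    )
    paths = write_benchmark(balanced, RESULTS / "balanced")
    print(f"balanced benchmark: {len(balanced)} records "
          f"(200 per category) -> {paths['snornas'].parent}")

    census_like = generate_snorna(GenerationSpec(seed=43, n=43))
    paths = write_benchmark(census_like, RESULTS / "census_mix")
    print(f"census-mix cohort: {len(census_like)} records "
          f"(yeast census proportions 2/6/18/17) -> {paths['snornas'].parent}")


if __name__ == "__main__":
    main()
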