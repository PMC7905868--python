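"""Case-ranking harness: published cases and generated ones.

The package ships the 20 published rare-disease case reports (HPO term
lists with an OMIM-coded diagnosis and the originally reported rank and
score). Ranking them requires a real HPO + Orphanet knowledge base; here the
same harness runs on generated cases against a synthetic knowledge base,
and the packaged table is shown with its side-by-side reference columns.
"""

import tempfile
from pathlib import Path

from rdmap.evaluation import (
    load_literature_cases,
    packaged_literature_cases,
    run_literature_cases,
)
from rdmap.fixtures import generate_cases, generate_knowledge_base

cases = packaged_literature_cases()
print(f"packaged case table: {len(cases)} published cases")
for c in cases[:3]:
    print(f"  {c.case_id}: {c.target_xref} ({c.target_name}), "
          f"{len(c.query_terms)} HPO terms, reported rank {c.reported_rank}")
print("  ...")

with tempfile.TemporaryDirectory() as tmp:
    kb, _ = generate_knowledge_base(
        tmp, n_diseases=60, terms_per_disease=8, n_clusters=1, seed=2,
    )
    case_path = Path(tmp) / "cases.tsv"
    generate_cases(kb, n_cases=20, terms_per_case=4, n_imprecise=1,
                   seed=3, path=case_path)
    report = run_literature_cases(kb, load_literature_cases(case_path),
                                  use_weights=False)

s = report.summary
print(f"\ngenerated cases (1 imprecise term each), {s['n_resolved']} resolved:")
print(f"  mean rank {s['mean_rank']:.1f}, median {s['median_rank']:.0f}, "
      f"worst {s['max_rank']:.0f}")
print(f"  mean target score {s['mean_score']:.3f} +/- {s['sd_score']:.3f}")
# rank 1 means the true diagnosis led the recommendation list; the score is
# the distance of the query to the target's annotation (0 = exact).
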