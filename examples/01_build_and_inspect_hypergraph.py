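"""Build a temporal concept hypergraph from records and inspect it.

Writes a handful of article-style records (id, year, concept list), reads
them back as a temporal hypergraph, applies the 5..30 size filter, and
prints summary statistics.  The printed counts show how records become
year-indexed hyperedges over a shared concept vocabulary.
"""

import json
import tempfile
from pathlib import Path

from hypertrail import filter_by_size, read_hyperedges
from hypertrail.synthetic import summarize

records = [
    {"id": "a1", "year": 2001, "concepts": ["TP53", "EGFR", "apoptosis",
                                            "lung neoplasm", "cisplatin"]},
    {"id": "a2", "year": 2001, "concepts": ["TP53", "MDM2", "apoptosis",
                                            "ubiquitin", "proteasome"]},
    {"id": "a3", "year": 2002, "concepts": ["EGFR", "gefitinib",
                                            "lung neoplasm", "mutation",
                                            "drug resistance"]},
    {"id": "a4", "year": 2003, "concepts": ["EGFR", "T790M", "drug resistance",
                                            "osimertinib"]},  # size 4: filtered
]

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "articles.jsonl"
    path.write_text("\n".join(json.dumps(r) for r in records) + "\n")
    th = read_hyperedges(path)

print(f"hyperedges read: {th.num_hyperedges}, concepts: {th.vocabulary.size}, "
      f"years {th.years[0]}-{th.years[-1]}")

filtered = filter_by_size(th, min_size=5, max_size=30)
print(f"after 5..30 size filter: {filtered.num_hyperedges} hyperedges "
      f"(the size-4 record is discarded as too sparse to be reliable)")
print("summary:", summarize(filtered))
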