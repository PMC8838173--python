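"""Generate the synthetic 189-record validation study and its tool observation.

Writes results/synthetic/{ref.jsonl, app.jsonl, links.csv} with the default
study composition (63/63/30/33 records per stratum, 15 barcode scans) and the
default error model (2% omissions, 5/189 intrusion rate, stratum-specific
grade mix, meat/fish weight overestimation).  Everything downstream
(03_evaluate_pipeline.py) starts from these files.
"""

from pathlib import Path

from dieteval.records import write_records
from dieteval.simulate import ErrorModel, StudyConfig, generate_reference, simulate_app

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20240

def main() -> None:
    cfg = StudyConfig(seed=SEED)
    ref = generate_reference(cfg)
    app, links = simulate_app(ref, ErrorModel(), seed=SEED + 1)

    OUT.mkdir(parents=True, exist_ok=True)
    write_records(ref, OUT / "ref.jsonl")
    write_records(app, OUT / "app.jsonl")
    links.to_csv(OUT / "links.csv", index=False)

    n_seg = sum(r.n_segments for r in ref)
    n_scan = sum(r.entry_mode == "scan" for r in ref)
    n_found = (links["grade"] != "I").sum()
    n_intr = (links["grade"] == "I").sum()
    print(f"reference study: {len(ref)} records, {n_seg} segments, {n_scan} scans")
    print(f"tool observation: {n_found} found ({100*n_found/n_seg:.1f}%), "
          f"{n_seg-n_found} omitted, {n_intr} intruded")
    print(f"files under {OUT}")


if __name__ == "__main__":
    main()
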