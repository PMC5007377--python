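#!/usr/bin/env python
"""Combine the per-comparison calls with the Boolean expression
(C1 AND (C2 OR C3)) AND C4 AND (C5 OR C6) into the organizer signature,
then benchmark recovery of the planted 31+17 genes over several seeds.

Writes the seed-0 signature JSON and a recovery table to results/.
"""

from pathlib import Path

import pandas as pd

import orgscreen as og

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

N_SEEDS = 5


def main():
    RESULTS.mkdir(exist_ok=True)
    cfg = og.PipelineConfig()
    sheet = og.SampleSheet.default_design()
    params = og.PlantedSignatureParams()

    rows = []
    for seed in range(N_SEEDS):
        matrix, truth = og.simulate_expression(
            sheet, params, cfg.expression, seed, cfg.comparisons
        )
        tables = og.run_screen(matrix, cfg)
        sig = og.derive_signature(og.calls_matrix(tables), cfg.expression,
                                  provenance=cfg.expression_text)
        report = og.recovery_metrics(sig, truth)
        rows.append({
            "seed": seed,
            "n_enriched": len(sig.enriched),
            "n_depleted": len(sig.depleted),
            "sensitivity_enriched": report.sensitivity_enriched,
            "sensitivity_depleted": report.sensitivity_depleted,
            "set_fdr": 0.0 if report.set_fdr is None else report.set_fdr,
        })
        if seed == 0:
            og.write_signature(sig, RESULTS / "signature_seed0.json")
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "signature_recovery.tsv", sep="\t", index=False)
    print("planted-signature recovery (31 enriched + 17 depleted planted):")
    print(table.to_string(index=False))
    print(f"mean sensitivity: enriched {table.sensitivity_enriched.mean():.3f}, "
          f"depleted {table.sensitivity_depleted.mean():.3f}; "
          f"mean set-FDR {table.set_fdr.mean():.3f}")


if __name__ == "__main__":
    main()
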