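"""End-to-end experiment with both sequential strategies.

Runs the whole pipeline on a reduced synthetic dataset and prints the
per-stage correct-classification tables for cross and external validation
in the standard report layout, plus each stage's external AUC.  (At the full
333-sample default this takes around a minute; here a smaller set keeps the
example quick.)
"""

from olivegrade.experiment import RunConfig, run_experiment

cfg = RunConfig(n_evoo=24, n_voo=24, n_loo=18, seed=3, n_blinds=5, max_lv=8)
bundle = run_experiment(cfg)

print(f"retained fingerprint points: {bundle['n_points_retained']}")
for strat, payload in bundle["strategies"].items():
    print(f"\nstrategy {strat} (latent variables {payload['n_lv']}):")
    for stage in ("stage1", "stage2"):
        block = payload["report"]["stages"][stage]
        for sset in ("cross_validation", "external"):
            table = block[sset]["table"]
            cells = "  ".join(
                f"{label}: {c['correct']}/{c['total']} ({c['percent']}%)"
                for label, c in table.items()
            )
            print(f"  {stage:<7} {sset:<17} {cells}")
        print(f"  {stage:<7} external AUC = {block['external']['auc']:.3f}")
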