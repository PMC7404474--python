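"""Fit one sequential cascade on a small dataset and grade new oils.

The pipeline: simulate -> COW-align to the medoid reference -> concatenate
the two columns -> select the signal region -> Kennard-Stone 75/25 split ->
fit strategy S2 (LOO vs no-LOO, then VOO vs EVOO).  Each prediction carries
the deciding stage's posterior probability; low-probability samples are the
ones a laboratory would forward to the sensory panel.
"""

from olivegrade import (
    Category,
    PLSDAConfig,
    Strategy,
    SyntheticConfig,
    fit_cascade,
    generate_dataset,
    kennard_stone_split,
    predict_cascade,
)
from olivegrade.experiment import RunConfig, preprocess_dataset

syn = SyntheticConfig(seed=9)
samples, manifest = generate_dataset(
    syn, {Category.EVOO: 16, Category.VOO: 16, Category.LOO: 12}, seed=9
)
cfg = RunConfig(seed=9, n_blinds=4, max_lv=5)
F, reference = preprocess_dataset(samples, cfg)
split = kennard_stone_split(F.X, 0.25, sample_ids=F.sample_ids)

model = fit_cascade(Strategy.S2, F, manifest, split, PLSDAConfig(max_lv=5, n_blinds=4))
print(f"fitted S2 cascade, latent variables per stage: {model.provenance['n_lv']}")

Fext = F.rows(split.external_ids)
cats = manifest.categories()
correct = 0
for pred in predict_cascade(model, Fext.X, split.external_ids):
    truth = cats[pred.sample_id].value
    mark = "ok " if pred.label.value == truth else "MISS"
    correct += pred.label.value == truth
    print(
        f"  {pred.sample_id:>9}: predicted {pred.label.value:<4} (true {truth:<4}) "
        f"p = {pred.probability:.2f} via {'->'.join(pred.path):<12} {mark}"
    )
print(f"external accuracy: {correct}/{len(split.external_ids)}")
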