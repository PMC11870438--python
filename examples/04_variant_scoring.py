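"""Score variants with a trained model and classify causal vs null.

Trains the desk-scale model, scores synthetic variants with known true
effects (ref vs alt predictions → per-track difference and log-ratio
summaries), and fits a random-forest classifier, reporting
cross-validated AUROC and the Spearman correlation between classifier
score and true effect magnitude.
"""

import numpy as np

from seq2cov import SyntheticSpec, build_model, generate_corpus, \
    generate_variants, squash
from seq2cov.model import desk_model_config, desk_train_config, train
from seq2cov.variants import predict_variant, snp_classifier

spec = SyntheticSpec(n_windows=96, window_len=8192, mean_instances=8.0, seed=11)
corpus = generate_corpus(spec)
targets = [squash(ts.values) for ts in corpus.counts]

model = build_model(desk_model_config(), seed=1).astype(np.float32)
train(model, corpus.windows, targets, list(spec.tracks),
      list(range(80)), list(range(80, 96)),
      desk_train_config(max_steps=450), seed=2)

variants = generate_variants(spec, corpus)
scores, labels, effects = [], [], []
for v in variants:
    win = corpus.windows[v["window"]]
    scores.append(predict_variant([model.predict], win, v["pos"], v["ref"],
                                  v["alt"], v["id"], crop=32))
    labels.append(v["label"])
    effects.append(abs(v["effect"]))

rep = snp_classifier(scores, labels, seed=5, target=effects)
print(f"{sum(labels)} motif-destroying and {len(labels) - sum(labels)} null variants")
print(f"random-forest AUROC (5-fold CV): {rep.auroc:.3f}")
print(f"Spearman(classifier score, |true effect|): {rep.spearman:.3f}")
print("AUROC near 1 means the model's ref-vs-alt prediction changes recover "
      "the planted causal variants; the Spearman term checks effect-size ranking.")
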