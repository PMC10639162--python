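"""Compare classifiers under 10-fold CV, then rank factors by Shapley values.

Uses the strong-signal scenario (near-deterministic labels, Bayes accuracy
~0.93): the regime in which a well-fitted classifier reaches ~0.9 accuracy.
Training folds are balanced by random oversampling; test folds are left
untouched.
"""

from sklearn.ensemble import RandomForestClassifier

from obesifact.classify import compare_models, default_model_specs
from obesifact.shap_rank import compute_shap, dependence_export, rank_features, top_k
from obesifact.synthetic import (generate_individual_records, records_to_frame,
                                 strong_signal_truth)

truth = strong_signal_truth(seed=0)
df = records_to_frame(generate_individual_records(3000, truth))
X = df[truth.individual_feature_names]
y = df["obese"].astype(int).to_numpy()

print("10-fold pooled metrics by model family (desk-scale tree counts):")
for res in compare_models(X, y, default_model_specs(trees=100, max_depth=8), k=10, seed=0):
    m = res.pooled
    print(f"  {res.model_name:20s} acc={m.accuracy:.3f} prec={m.precision:.3f} "
          f"rec={m.recall:.3f} f1={m.f1:.3f}")

model = RandomForestClassifier(n_estimators=100, max_depth=8, random_state=0)
model.fit(X.to_numpy(), y)
shap = compute_shap(model, X)
ranking = rank_features(shap)
print("\ntop-5 factors by mean |Shapley attribution| (probability-of-obesity margin):")
for name in top_k(ranking, 5):
    imp = dict(ranking.ordered)[name]
    true_eff = truth.individual_effects.get(name, 0.0)
    print(f"  {name:26s} importance={imp:.4f}   true logistic effect={true_eff:+.2f}")

dom = top_k(ranking, 1)[0]
dep = dependence_export(shap, X, dom)
print(f"\ndependence of '{dom}': attribution rises with the response value "
      f"(corr={dep.corr().iloc[0, 1]:+.2f}), i.e. higher codes push predictions "
      "toward obesity")
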