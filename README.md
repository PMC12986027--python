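# cappm — conformance-aware predictive process monitoring

`cappm` predicts early clinical deterioration from **incomplete care
pathways**: given only the first k events of a patient's hospital trajectory
(an event-log *prefix*), it estimates the probability that the case will later
reach a deterioration-defining activity such as intensive-care admission. Its
distinguishing idea is that *how* care is being delivered — deviations from
the institution's usual pathway — carries predictive signal beyond laboratory
values and timing, so the feature set combines:

* **behavioral** features: event count n, distinct activities, revisit ratio
  R = 1 − |{a₁…aₙ}|/n, key-step indicators;
* **temporal** features: elapsed hours h = (tₖ − t₁)/3600, mean inter-event
  gap, time since last activity;
* **clinical** features: mean/min/max/last of laboratory attributes (CRP,
  Leucocytes, LacticAcid, …) within the prefix;
* **conformance** features: the cost (and ln(1+cost)) of an optimal alignment
  of the prefix against a reference Petri net discovered from the full log by
  inductive mining, the synchronous/model/log move counts, and per-case trends
  of cost over prefix length (`align_cost_slope`, `align_cost_delta`);
* **declarative** features: response-constraint violation ratios — the
  fraction of activations a (e.g. ER Sepsis Triage) not followed by their
  response b (e.g. IV Antibiotics) within the prefix;
* **pathway cluster**: unsupervised K-means profile (k = 3) of the case's
  pre-deterioration structure.

Cases are labelled y = 1 iff the trace contains an activity in the
deterioration set D = {Admission IC, Release D}. Prefixes of lengths
k ∈ {3, 5, 10} are generated with strict leakage control (no prefix contains
a deterioration event; positives keep only prefixes strictly before the first
one), split at case level, and scored at prefix level with AUROC, AUPRC,
Brier score, reliability bins and a thresholded confusion matrix. Tree-path
attributions (additive per-feature contributions) explain the fitted models.

The audience is researchers in clinical process mining / predictive process
monitoring who want a dependency-light, fully testable pipeline: the
inductive miner, the Petri-net alignment search and the declarative checker
are implemented in the package and certified against brute-force oracles in
the test suite.

## Worked example

Generate a synthetic emergency-department log with known ground truth (the
generator emulates a sepsis-style pathway: triage entry sequence, laboratory
loops with numeric values, IV treatment, admission/release outcomes, and
configurable coupling between pathway deviations and deterioration), then run
the full pipeline:

```python
from cappm import GeneratorConfig, generate, PipelineConfig, run_pipeline

log, truth = generate(GeneratorConfig(n_cases=500, seed=7))
cfg = PipelineConfig(algorithms=("gradient_boosting", "adaboost"))
result = run_pipeline(log, cfg)

for (fs, algo), rep in sorted(result["reports"].items()):
    print(f"{fs:>8} {algo:>17}  AUROC {rep.auroc:.3f}  AUPRC {rep.auprc:.3f}  Brier {rep.brier:.3f}")
cm = result["reports"][("cappm", "gradient_boosting")].confusion
print(f"confusion @0.5: tp={cm.tp} fp={cm.fp} tn={cm.tn} fn={cm.fn} "
      f"sens={cm.sensitivity:.2f} spec={cm.specificity:.2f}")
ew = result["early_warning"]
print(f"early-warning window: median {ew.median:.2f} h (IQR {ew.q1:.2f}-{ew.q3:.2f})")
```

Output:

```
baseline          adaboost  AUROC 0.798  AUPRC 0.471  Brier 0.155
baseline gradient_boosting  AUROC 0.763  AUPRC 0.414  Brier 0.082
   cappm          adaboost  AUROC 0.871  AUPRC 0.677  Brier 0.143
   cappm gradient_boosting  AUROC 0.870  AUPRC 0.680  Brier 0.052
confusion @0.5: tp=26 fp=0 tn=396 fn=24 sens=0.52 spec=1.00
early-warning window: median 7.02 h (IQR 4.25-11.05)
```

Reading this: the full (cappm) feature set improves ranking over the baseline
(static + event-level attributes only) for both models — here +0.11 AUROC for
gradient boosting — because part of the synthetic deterioration risk is
expressed only through pathway deviations that alignment costs and response
violations detect. At the default 0.5 threshold the model is specific but
conservative (few false alarms, roughly half of deteriorations flagged), and
flagged cases are identified a median of ~7 hours before the deterioration
event. On logs generated with *zero* deviation–outcome coupling the same
pipeline scores AUROC ≈ 0.5: the machinery itself manufactures no signal.

The same stages are available from the shell:

```bash
cappm synth --n 1050 --prevalence 0.123 --coupling moderate --seed 7 --out log.xes
cappm discover --log log.xes --out net.pnml
cappm align --log log.xes --net net.pnml --out alignments.jsonl
cappm evaluate --log log.xes --features cappm --model gb --seed 1 --out-dir run/
```

Real logs are read with `cappm.read_xes` (XES 2.0) or `cappm.read_csv`
(case/activity/timestamp column mapping); all downstream stages are agnostic
to the source.

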