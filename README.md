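# laolink

Patient matching (deduplication) for Lao-script child health registries.

Pediatric health-information exchange in Lao PDR shares demographic records
— child's name, date of birth, sex, village, parents' names — across
facilities without a national patient identifier. Duplicate records are
common and hard to resolve automatically: Lao is a tonal script with
confusable vowel signs (the name *Souksan* is attested as both ສຸກສັນ and
ສູກສັນ), romanization is inconsistent, family names and contact numbers are
largely missing, newborns are often registered under a placeholder name
("Eanoi", ແອນ້ອຍ, "baby") and renamed later, and twins share nearly every
quasi-identifier while being distinct children.

`laolink` implements the three standard linkage strategies for this
setting, as scikit-learn-style estimators over pandas DataFrames:

- **Deterministic** (`DeterministicMatcher`) — candidate pairs are blocked
  on exact (DOB, sex, village); within a block, the child's name and both
  parents' names are each compared into one of three states (match /
  non-match / not available) and the state triple is mapped to a link
  decision by a 27-row decision table. The default table is the majority
  rule `#match > #non-match`, which reproduces the 21 criteria (10 match,
  11 non-match) used by human reviewers for this kind of registry.
- **Probabilistic** (`FellegiSunterMatcher`) — Fellegi–Sunter linkage,
  implemented from scratch. Pairs blocked on (DOB, village) are summarized
  as comparison vectors γ with graded agreement levels (exact / Jaro–Winkler
  ≥ 0.88 / ≥ 0.70 / other, plus not-available). For each field *i* and level
  *l*, EM estimates m<sub>il</sub> = P(γ<sub>i</sub>=l | match) and
  u<sub>il</sub> = P(γ<sub>i</sub>=l | non-match) under conditional
  independence. Each pair gets the match weight
  w(γ) = Σ<sub>i</sub> log₂(m<sub>iγᵢ</sub>/u<sub>iγᵢ</sub>), converted to a
  posterior via the prior match probability λ, which is estimated from a
  recall-adjusted deterministic proxy (λ = proxy-pair count / recall /
  candidate-pair count, recall defaulting to 0.7).
- **Hybrid** (`HybridMatcher`) — deterministic rules first; probabilistic
  links are unioned in only between records the rules left unmatched, and
  each probabilistic link can be audited (or, in strict mode, filtered)
  against the decision table.

Accepted links are closed transitively into entity clusters. Evaluation
against a gold-standard partition is **record-level**: a record is positive
when it belongs to a multi-record cluster, and precision / recall / F1 and
PR curves are computed over records, not pairs.

Because real registries of this kind are access-controlled, the package
ships a synthetic registry generator (`generate_registry`) that emulates
their structure — duplicate-cluster fraction and size distribution, field
incompleteness, placeholder-name rates, twins, and Lao-specific spelling
noise — with a known truth partition, so the whole pipeline is testable
end to end.

## Worked example

```python
import io
import laolink as ll

cfg = ll.GeneratorConfig(n_records=5000)
records, truth = ll.generate_registry(cfg, seed=42)

buf = io.StringIO()
records.to_csv(buf, index=False)
buf.seek(0)
norm = ll.LaoNameNormalizer().fit_transform(ll.read_records(buf))

hybrid = ll.HybridMatcher().fit(norm)
det, prob = hybrid.deterministic_, hybrid.probabilistic_

print(f"records in duplicate clusters (truth): "
      f"{len(truth.partition.linked_records())} "
      f"({len(truth.partition.linked_records()) / len(norm):.2%})")
print(f"prior match probability (lambda): {prob.lambda_:.3f}")
for name, part in [("deterministic", det.partition_),
                   ("probabilistic", prob.partition_),
                   ("hybrid", hybrid.partition_)]:
    m = ll.metrics(ll.record_confusion(part, truth.partition))
    print(f"{name:>13}: precision={m.precision:.3f} "
          f"recall={m.recall:.3f} f1={m.f1:.3f}")
```

prints

```
records in duplicate clusters (truth): 781 (15.62%)
prior match probability (lambda): 0.935
deterministic: precision=0.997 recall=0.795 f1=0.885
probabilistic: precision=0.996 recall=0.960 f1=0.978
       hybrid: precision=0.996 recall=0.953 f1=0.974
```

The generator planted 15.62% of records in duplicate clusters with spelling
noise on names. Exact rules miss duplicates whose names were corrupted on
two or more fields (recall 0.80), while graded Jaro–Winkler agreement
absorbs that noise (recall 0.95+) at essentially no precision cost — the
qualitative gap that motivates probabilistic and hybrid matching in this
setting.

A command-line interface mirrors the library:

```
laolink simulate --out reg.csv --truth truth.csv --n 5000 --seed 42
laolink match-hybrid --input reg.csv --output clusters.csv
laolink evaluate --pred clusters.csv --gold gold.csv --report report/
```

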