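# fminer

Mining multi-ingredient herbal prescription datasets.

Clinical collections of traditional Chinese medicine (TCM) prescriptions
are transaction data: each formula is a set of herbs, recorded with
inconsistent nomenclature and the occasional duplicated entry. `fminer`
provides the full analysis chain a prescription-mining study needs, as a
Python library with a matching `fminer` command line:

* **standardize** — synonym resolution against a lookup table, duplicate
  collapse, long ↔ wide (binary incidence) conversion, frequency tables;
* **attributes** — statistics over the four natures, five flavors,
  meridian tropism and efficacy classes of the herbs in a dataset,
  weighted (by occurrence count) and unweighted;
* **rules** — Apriori frequent-itemset and association-rule mining, with
  batch exploration of a whole minimum-support × minimum-confidence grid
  at once;
* **correlation** — phi coefficient matrices with chi-square p-values and
  significance stars; co-occurrence counts and networks;
* **cluster** — agglomerative clustering with the seven classical
  linkages (ward.D, ward.D2, single, complete, average, centroid, median)
  and a vote of internal validity indices to recommend the number of
  clusters;
* **similarity** — Jaccard matrices between formulas, inter-group
  similarity scores, role-weighted similarity to a core formula, and
  thresholded similarity networks with degree centrality;
* **simdata** — a synthetic prescription generator (Zipf-distributed
  background herbs, planted core combinations, synonym/duplicate noise)
  with full ground truth, plus small packaged reference fixtures.

## The statistics

For transactions $T_1,\dots,T_N$ (formulas as herb sets) and itemsets
$A, C$:

* support$(A) = |\{i : A \subseteq T_i\}| / N$; a rule $A \Rightarrow C$
  has confidence $= \mathrm{supp}(A \cup C)/\mathrm{supp}(A)$ and lift
  $= \mathrm{confidence}/\mathrm{supp}(C)$, with lift $> 1$ indicating
  positive association.
* The phi coefficient of two binary occurrence columns with 2×2 table
  $(a, b, c, d)$ is
  $\phi = (ad - bc)/\sqrt{(a+b)(c+d)(a+c)(b+d)}$,
  and $\chi^2 = N\phi^2$ with 1 df gives its p-value.
* The Jaccard coefficient of two formulas is
  $J(A, B) = |A \cap B| / |A \cup B|$; the similarity between two formula
  groups $A_1..A_n$ and $B_1..B_m$ is the mean over all cross pairs,
  $\mathrm{grpSimScore} = \frac{1}{nm}\sum_{i=1}^{n}\sum_{j=1}^{m} J(A_i, B_j)$.
* Role-weighted similarity scores a formula $F$ against a core formula
  whose herbs carry Monarch/Minister/Assistant/Envoy weights $w$:
  $\mathrm{score}(F) = \sum_{h \in \mathrm{core} \cap F} w(h) \big/
  \sum_{h \in \mathrm{core} \cup F} w(h)$ (herbs outside the core take the
  unassigned weight). With equal weights this is exactly $J$.

## Worked example

```python
import fminer as fm

classics = fm.load_fixture("classics")     # 15 classical formulas
print(fm.freq_table(classics).head(5).to_string(index=False))

t = fm.trans_rules(classics)
rules = fm.extract_rules(t, min_support=0.13, min_confidence=0.6,
                         retain_lift_gt1=True)
for r in rules[:2]:
    print(sorted(r.antecedent), "->", sorted(r.consequent),
          f"support={r.support:.3f} confidence={r.confidence:.2f} lift={r.lift:.2f}")

jr = fm.calc_jaccard(classics, threshold=0.3)
print(jr.pair_table.head(3).to_string(index=False))
```

prints

```
   term  count  relative_frequency
 Gancao     10            0.666667
 Fuling      4            0.266667
Baishao      3            0.200000
 Baizhu      3            0.200000
 Chenpi      3            0.200000
['Baishao', 'Chuanxiong'] -> ['Shudihuang'] support=0.133 confidence=1.00 lift=7.50
['Baishao', 'Chuanxiong', 'Danggui'] -> ['Shudihuang'] support=0.133 confidence=1.00 lift=7.50
        id_a              id_b  jaccard
   Siwu Tang Taohong Siwu Tang 0.666667
Sijunzi Tang Buzhong Yiqi Tang 0.375000
  Baihu Tang   Suanzaoren Tang 0.333333
```

Gancao (licorice) appears in 10 of the 15 formulas — the classic
harmonizer. The top rules recover the Siwu Tang core (the four-herb blood
tonic), each pair of whose members predicts the rest with confidence 1
and lift 7.5 since the combination occurs together and rarely apart. The
Jaccard table finds Taohong Siwu Tang, the extension of Siwu Tang with
two blood-moving herbs, as the most similar pair (4 shared herbs out of
6 total).

The same analyses run from the shell, e.g.:

```sh
fminer simulate --n 2000 --vocab 60 --seed 42 --out sim/
fminer standardize --input sim/sim_long.csv --drop-unmatched --out run/
fminer rules explore --input sim/sim_long.csv \
    --supports 0.05,0.1,0.2 --confidences 0.5,0.7,0.9 --out run/
fminer cluster kselect --input sim/sim_long.csv --kmin 2 --kmax 8 --out run/
fminer jaccard --input sim/sim_long.csv --threshold 0.8 --out run/
```

Each command writes CSV (networks also as GraphML) and appends a stage
record with parameters and input checksums to `run/manifest.json`.

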