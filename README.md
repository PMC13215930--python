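# ismanp

Interpretive Structural Modeling (ISM) and the Analytic Network Process
(ANP) for injury risk-factor systems, with the questionnaire psychometrics
that precede them and synthetic-data generators that make every stage
testable offline.

The package is aimed at public-health and injury-prevention researchers who
elicit pairwise influence judgments among risk factors (for example factors
classified by the Haddon matrix: host, medium/agent, physical environment,
social environment) and want to turn them into (a) a multi-level hierarchy
showing how risk is transmitted from root causes to surface events, and
(b) global importance weights for prioritizing interventions. It ships a
fully worked 18-factor example system for preschool-children drowning risk.

## The methods

**Psychometrics.** Likert questionnaire responses are screened with
Cronbach's α = (k/(k−1))(1 − Σsᵢ²/s_T²), the Kaiser-Meyer-Olkin sampling
adequacy statistic (correlations vs anti-image partial correlations), and
Bartlett's sphericity test χ² = −(n−1−(2p+5)/6)·ln|R|. Common factors are
extracted by principal components (eigenvalue > 1 or cumulative-variance
retention) and varimax-rotated (Kaiser's pairwise closed-form algorithm).

**ISM.** Relation codes V/A/X/O between factor pairs become a binary
adjacency matrix A; the reachability matrix M = (A+I)^k is the Boolean
fixed point (A+I)^k = (A+I)^{k+1}. Row and column reads of M give each
factor's reachable set R(Fᵢ) and antecedent set Q(Fᵢ); iteratively
extracting the factors with R(Fᵢ) ∩ Q(Fᵢ) = R(Fᵢ) and deleting them yields
the level partition, surface (consequence) level first. The hierarchy
digraph is the transitive reduction of the strict reachability relation.

**ANP.** Saaty 1-9 reciprocal judgment matrices give local priorities via
the principal eigenvector, gated by the consistency ratio
CR = CI/RI < 0.1 with CI = (λmax−m)/(m−1). Column j of the unweighted
supermatrix W₀ distributes factor j's influence over the factors it
reaches; cluster weights scale the blocks (W = a_rc·W₀ blocks, columns
renormalized); the limit W∞ = lim W^k (Cesàro-averaged when the power
sequence is periodic) gives every factor's global weight.

## Worked example

```python
import warnings
from ismanp import fixtures, ism, anp
from ismanp.synthetic import random_consistent_judgments

fx = fixtures.load_fixtures()                      # bundled 18-factor system
M = ism.reachability_from_sets(fx.reachable_sets)  # reachability matrix

with warnings.catch_warnings():
    warnings.simplefilter("ignore")                # bundled sets not fully closed
    model = ism.InterpretiveStructuralModel(input="reachability").fit(M)
for i, level in enumerate(model.levels_, start=1):
    print(f"L{i}: {', '.join(level)}")

network = anp.build_network(M, fx.cluster_of, fx.cluster_order)
judgments = random_consistent_judgments(network, seed=42)
weights = anp.anp_pipeline(network, judgments).weights
print("sources weigh zero:", [f for f in network.sources
                              if weights.loc[f, "weight"] == 0.0])
top = weights.sort_values("weight", ascending=False).head(3)
for f, row in top.iterrows():
    print(f"{f}: weight={row['weight']:.4f} rank={int(row['rank'])}")
```

prints

```
L1: F4, F5, F18
L2: F3, F13, F17
L3: F2, F6, F7, F8, F10, F11, F12
L4: F1, F9, F14
L5: F15, F16
sources weigh zero: ['F1', 'F8', 'F15', 'F16']
F5: weight=0.4438 rank=1
F4: weight=0.4227 rank=2
F18: weight=0.1335 rank=3
```

Level 1 holds the surface factors (children's risky behaviors F4, lack of
immediate protection F5, medical rescue F18); level 5 the roots (community
safety system F15, family economic background F16). The four factors that
nothing in the network influences (F1, F8, F15, F16) receive global weight
exactly 0 — a structural fact of the influence-oriented supermatrix that
holds for *any* positive judgment values, and the pure power limit
concentrates the remaining mass on the absorbing surface factors (see
`docs/methods.md` for what that does and does not imply about mid-level
factors). The same run is available from the shell:

```
ismanp pipeline --config demo.json     # {"out_dir": "out", "use_example": true,
                                       #  "seeded_random_judgments": true, "seed": 42}
```

plus `ismanp efa`, `ismanp ism run`, `ismanp ism from-reachability`,
`ismanp anp run`, `ismanp simulate responses|judgments|dag` and
`ismanp fixtures show`.

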