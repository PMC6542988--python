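# sdfa — sparse direct feedback alignment

Training deep networks with backpropagation requires every hidden neuron to
see the transposed weights of all deeper layers — the *weight transport
problem* — which forces global data movement and rules out near-memory
hardware where each neuron keeps its own weights. **Direct feedback alignment
(DFA)** sidesteps this by carrying the output error straight to each hidden
layer through a fixed random matrix `B_l`. This package implements **sparse
DFA (SDFA)** and its single-connection extreme (**SSDFA**), where `B_l` is
mostly zeros — down to one nonzero per row, so each neuron's error signal is
the product of three scalars:

```
δa_l,i = B_l,i,j · e_j · f'(a_l,i)
```

It is aimed at researchers in bio-plausible learning and neuromorphic
hardware who want a small, fully tested reference implementation with:

- forward/backward passes under **BP**, **DFA**, and **SDFA/SSDFA** credit
  rules (`δa_l = W_{l+1}ᵀ δa_{l+1} ⊙ f'(a_l)` vs. `δa_l = B_l e ⊙ f'(a_l)`);
- construction of random feedback matrices with **prescribed rank R and
  sparsity S**, subject to the feasibility rule `R·(1−S) ≥ 1` (every error
  signal must reach at least one neuron);
- the **alignment angle** diagnostic `∠(B_l, ∏_{i>l} W_i)` between the
  vectorized feedback matrix and the product of downstream forward weights;
- an analytic **hardware cost model** counting reads, writes,
  multiply-accumulates and data movement per training example;
- synthetic classification tasks (Gaussian clusters, teacher networks) and an
  optional reader for MNIST-style IDX files.

## Worked example

```python
import sdfa

# A 25-neuron hidden layer fed by 10 error signals through one connection
# per neuron: 9 of every 10 entries are zero, yet the matrix is full rank.
fb = sdfa.generate_ssdfa(25, 10, seed=0)
print(fb.measured_sparsity, fb.measured_rank)     # 0.9 10

# Hardware cost of the AlexNet fully connected stack (1000 classes).
arch = (sdfa.LayerSpec(9216, 4096, "relu"),
        sdfa.LayerSpec(4096, 4096, "relu"),
        sdfa.LayerSpec(4096, 1000, "linear"))
bp    = sdfa.network_costs(arch, "BP")
dfa   = sdfa.network_costs(arch, "DFA")
ssdfa = sdfa.network_costs(arch, "SDFA", feedback_nnz_per_row=1)
print(round(sdfa.reduction_factor(dfa, ssdfa, "movement")))   # 1000
print(sdfa.format_2sig(sdfa.reduction_factor(bp, ssdfa, "movement")))  # 6400
print(round(sdfa.reduction_factor(bp, ssdfa, "macs"), 3))     # 2.0
```

Moving from dense DFA to SSDFA cuts backward-pass data movement by the number
of classes (each neuron receives 1 error word instead of 1000); against BP on
a von Neumann machine the reduction is ≈6400×; the MAC reduction is bounded
by 2× because the partial error at every forward weight must still be
computed.

Training end to end (the bundled synthetic task: 784 features, 10 Gaussian
clusters, margin/noise = 6, 6000 samples, a 784-400-10 tanh network):

```python
from sdfa.experiments import ExperimentConfig, train
cfg = ExperimentConfig(
    architecture=(sdfa.LayerSpec(784, 400, "tanh"),
                  sdfa.LayerSpec(400, 10, "linear")),
    rule="DFA", ssdfa=True, learning_rate=0.1, epochs=5, batch_size=64, seed=1)
history, params, feedbacks = train(cfg)
print(history[-1].test_acc)      # 0.998
print(history[0].mean_angle, history[-1].mean_angle)  # ~90° shrinking as W aligns to B
```

On this task BP reaches 100.0% test accuracy, dense DFA 99.4% and SSDFA
99.8% (seed 1) — sparsity of the feedback barely moves the needle, while the
mean alignment angle falls from ≈90° as the forward weights align to the
fixed random feedback.

## Command line

```bash
sdfa train -c config.yaml -o runs/            # per-epoch metrics CSV
sdfa sweep -c config.yaml --ranks 1,2,5,10 --sparsities 0,0.5,0.9
sdfa cost  -c config.yaml -o costs.csv        # per-layer cost table + factors
sdfa gen-feedback -N 400 -M 10 -R 5 -S 0.5 -o fb.txt
sdfa gen-task -o task --n-samples 6000
```

Configs are YAML; every run writes a resolved copy of its config next to its
outputs, and re-running a config reproduces the CSVs byte for byte.

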