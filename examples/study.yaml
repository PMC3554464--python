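# Full factorial bias-study grid; omit any key to accept its default.
dists: [gamma, normal]
n_clusters: [10, 30, 50]
rhos: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
cluster_size: 10
reps: 5000
total_variance: 1000
mu: 10
gamma_shape: 1.67
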