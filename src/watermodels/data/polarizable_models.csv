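name,n,q,Q_D,z2,y1,alpha,mu,sigma,epsilon,k,provenance
alpha,3,0.1975,1.6825,0.9803,1.3439,0.94,1.86,3.3836,0.7113,1000,reference-tables/polarizable/limited-optimal
alpha_and_mu,3,0.1700,2.6261,1.0565,1.4484,2.2900,1.7258,3.3786,1.0435,1000,reference-tables/polarizable/globally-optimal
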