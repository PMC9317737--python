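mirna	log2fc	avg_expr	adj_p	condition_associated
miR-106b-3p	1.589	8.731	8.61e-15	false
miR-140-3p	1.073	10.098	2.75e-13	false
miR-142-5p	0.962	10.651	4.96e-12	false
miR-532-5p	1.288	7.237	4.96e-12	false
miR-17-5p	0.952	7.892	7.84e-12	false
miR-19b-3p	1.128	8.696	1.93e-09	false
miR-30c-5p	0.950	7.325	2.48e-09	false
miR-324-5p	1.304	7.186	2.50e-09	false
miR-192-5p	0.941	8.944	1.37e-08	false
miR-660-5p	1.305	7.620	3.45e-10	false
miR-186-5p	1.228	8.052	2.75e-13	true
miR-425-5p	1.282	11.246	4.96e-12	true
miR-25-3p	1.212	12.939	1.26e-11	true
miR-363-3p	1.237	7.882	4.52e-11	true
miR-183-5p	1.550	9.382	9.34e-11	true
miR-451a	1.372	13.002	3.65e-10	true
miR-182-5p	1.341	10.585	2.48e-09	true
miR-191-5p	0.929	11.790	4.68e-09	true
miR-194-5p	0.937	7.679	1.85e-08	true
miR-20b-5p	0.932	7.430	1.96e-08	true
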