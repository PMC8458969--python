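# Curated per-site C-to-U editing efficiencies for wild-type (HD12) and mutant
# (Gmpgl2) soybean seedlings at two leaf stages, transcribed cell-for-cell from
# the published comparison table. Percent strings are kept exactly as printed
# (including the two bare "0%" cells); the loader normalises them to fractions.
# The "label" column is the printed annotation: an amino-acid substitution or
# "Unchanged" for coding sites, otherwise the printed region word.
gene	position	HD12-S1	HD12-S2	Gmpgl2-S1	Gmpgl2-S2	label
ndhC	10779	29.58%	28.57%	28.98%	28.73%	Unchanged
ndhC	11062	95.76%	97.45%	94.38%	91.28%	Ser-Leu
ndhK	12704	2.89%	11.38%	0.41%	4.91%	Downstream
ndhJ	14209	2.88%	17.12%	2.62%	10.17%	Intergenic
rps14	23651	87.54%	75.43%	77.29%	68.19%	Ser-Leu
rpoB	34587	63.16%	52.80%	66.03%	52.01%	Ser-Phe
rpoB	34800	60.97%	70.40%	71.28%	63.21%	Ser-Leu
rpoB	34815	59.00%	75.71%	63.50%	70.22%	Ser-Leu
rpoB	36249	89.79%	86.59%	80.93%	80.49%	Ser-Phe
rpoC1	37529	75.08%	75.36%	75.79%	67.91%	Ser-Leu
rpoC1	38778	74.02%	62.27%	60.08%	47.24%	Ser-Leu
rpoC2	43303	3.32%	15.51%	3.11%	2.56%	Ser-Leu
rps2	45133	94.23%	95.49%	87.95%	85.52%	Thr-Ile
rps2	45247	87.55%	93.77%	81.33%	80.77%	Ser-Leu
atpF	48596	86.50%	90.61%	72.21%	74.35%	Pro-Leu
rps16	55714	81.84%	89.00%	90.59%	76.07%	intron
rps16	56313	79.02%	77.48%	0.00%	0.00%	Ser-Leu
accD	57518	87.08%	90.13%	85.64%	74.74%	Ser-Leu
psaI	58512	89.09%	91.48%	85.18%	83.38%	His-Tyr
rps18	66641	84.39%	72.97%	57.89%	50.63%	Ser-Leu
petB	74300	26.13%	26.77%	22.00%	24.78%	Unchanged
petB	74899	93.59%	96.18%	93.81%	88.49%	Ser-Leu
rps12	106113	36.84%	0%	0.00%	0%	Intergenic
ndhA	115982	79.04%	89.52%	77.35%	84.16%	Ser-Leu
ndhA	117982	62.86%	89.87%	63.66%	85.68%	Ser-Phe
ndhE	119873	64.74%	80.82%	42.93%	52.57%	Pro-Leu
ndhD	120618	41.35%	83.96%	18.75%	55.69%	Thr-Met
ndhD	120999	73.33%	84.51%	57.33%	71.82%	Thr-Ile
ndhD	121290	65.86%	80.65%	69.50%	82.43%	Ser-Leu
ndhD	121494	64.94%	81.79%	55.67%	78.83%	Ser-Leu
ndhD	121914	44.95%	46.69%	28.91%	37.30%	Ser-Leu
ndhF	124681	44.09%	87.06%	35.59%	55.98%	Ser-Leu
rps12	138416	80.00%	71.91%	51.23%	49.59%	Intron
ndhB	139627	92.33%	80.00%	68.57%	78.67%	Ser-Leu
ndhB	140020	83.63%	96.65%	74.06%	90.27%	Thr-Met
ndhB	140064	64.08%	91.35%	50.08%	81.80%	His-Tyr
ndhB	140215	73.86%	92.19%	47.35%	71.96%	Pro-Leu
ndhB	140224	76.93%	89.32%	61.82%	72.92%	Ser-Phe
ndhB	140999	78.49%	91.12%	61.73%	75.21%	Ser-Leu
ndhB	141005	82.14%	90.21%	60.49%	66.95%	Ser-Leu
ndhB	141281	77.03%	87.68%	53.58%	59.70%	Ser-Leu
ndhB	141424	61.89%	84.78%	33.91%	51.22%	His-Tyr
ndhB	141650	69.47%	91.50%	49.78%	79.97%	Pro-Leu
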