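# Published reference values from the eastern-China (Jiangsu/Shanghai/
# Zhejiang) heat-health-risk assessment this pipeline re-implements.
# table,row,col,value
table,row,col,value
risk_proportions_pct,lowest,2010,7.57
risk_proportions_pct,low,2010,25.24
risk_proportions_pct,medium,2010,19.05
risk_proportions_pct,high,2010,17.04
risk_proportions_pct,highest,2010,31.11
risk_proportions_pct,lowest,2015,6.49
risk_proportions_pct,low,2015,21.39
risk_proportions_pct,medium,2015,21.53
risk_proportions_pct,high,2015,19.01
risk_proportions_pct,highest,2015,31.58
risk_proportions_pct,lowest,2019,6.62
risk_proportions_pct,low,2019,6.18
risk_proportions_pct,medium,2019,19.04
risk_proportions_pct,high,2019,19.71
risk_proportions_pct,highest,2019,48.44
dominance_pct,hazard,2010,11.42
dominance_pct,social_vulnerability,2010,88.49
dominance_pct,exposure,2010,0.09
dominance_pct,hazard,2015,13.92
dominance_pct,social_vulnerability,2015,85.93
dominance_pct,exposure,2015,0.15
dominance_pct,hazard,2019,27.40
dominance_pct,social_vulnerability,2019,72.49
dominance_pct,exposure,2019,0.11
pca_contribution_pct,pc1,all,42.714
pca_contribution_pct,pc2,all,15.405
pca_contribution_pct,pc3,all,14.094
pca_contribution_pct,pc4,all,9.692
pca_eigenvalue,pc1,all,5.126
pca_eigenvalue,pc2,all,1.849
pca_eigenvalue,pc3,all,1.691
pca_eigenvalue,pc4,all,1.163
weight,gdp,social_vulnerability,0.14
weight,disposable_income,social_vulnerability,0.17
weight,physicians,social_vulnerability,0.20
weight,hospital_beds,social_vulnerability,0.16
weight,older_adults,social_vulnerability,0.13
weight,female,social_vulnerability,0.11
weight,unemployment,social_vulnerability,0.09
weight,ndvi,exposure,0.12
weight,population_density,exposure,0.32
weight,water_resources,exposure,0.30
weight,agricultural_practitioners,exposure,0.01
weight,construction_practitioners,exposure,0.25
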