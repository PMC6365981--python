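# Study-level summary table for the meta-analysis modules.
# Study identifiers, measured parameters and per-study patient totals follow
# the published study list (14 studies; 9 ADC studies / 290 patients,
# 5 CBF studies / 252 patients). The per-subtype splits and all mean/sd
# values are SYNTHETIC stand-ins on realistic scales: the source reports
# subtype-level point estimates only graphically.
# ADC values in mm^2/s; nCBF dimensionless.
study_id,parameter,subtype,who_grade,n,mean,sd
Bull2012,ADC_ROI_mean,pilocytic_astrocytoma,I,20,0.00148,0.00026
Bull2012,ADC_ROI_mean,medulloblastoma,IV,18,0.00068,0.00012
Bull2012,ADC_ROI_mean,ependymoma,II,16,0.00112,0.00021
Bull2012,ADC_ROI_min,pilocytic_astrocytoma,I,20,0.00118,0.00024
Bull2012,ADC_ROI_min,medulloblastoma,IV,18,0.00054,0.00010
Bull2012,ADC_ROI_min,ependymoma,II,16,0.00091,0.00018
Calmon2017,ADC_ROI_mean,diffuse_midline_glioma,IV,18,0.00117,0.00020
Chang2003,ADC_ROI_mean,medulloblastoma,IV,3,0.00073,0.00014
Chang2003,ADC_ROI_mean,ependymoma,II,3,0.00105,0.00019
Chen2010,ADC_ROI_mean,medulloblastoma,IV,12,0.00071,0.00013
Chen2010,ADC_ROI_mean,atrt,IV,10,0.00060,0.00011
Chen2010,ADC_ROI_min,medulloblastoma,IV,12,0.00056,0.00011
Chen2010,ADC_ROI_min,atrt,IV,10,0.00047,0.00009
Choudhri2015,ADC_ROI_mean,pilocytic_astrocytoma,I,12,0.00141,0.00024
Choudhri2015,ADC_ROI_mean,medulloblastoma,IV,8,0.00066,0.00012
Koral2013,ADC_ROI_mean,pilocytic_astrocytoma,I,40,0.00152,0.00027
Koral2013,ADC_ROI_mean,medulloblastoma,IV,35,0.00072,0.00013
Koral2013,ADC_ROI_mean,ependymoma,II,20,0.00115,0.00022
Koral2013,ADC_ROI_min,pilocytic_astrocytoma,I,40,0.00121,0.00026
Koral2013,ADC_ROI_min,medulloblastoma,IV,35,0.00057,0.00010
Koral2013,ADC_ROI_min,ependymoma,II,20,0.00088,0.00017
Kralik2014,ADC_ROI_min,atrt,IV,9,0.00049,0.00010
Kralik2014,ADC_ROI_min,medulloblastoma,IV,10,0.00053,0.00010
Poretti2013,ADC_ROI_mean,atrt,IV,6,0.00058,0.00010
Poretti2013,ADC_ROI_mean,medulloblastoma,IV,10,0.00069,0.00012
Poretti2013,ADC_ROI_mean,pilocytic_astrocytoma,I,8,0.00139,0.00023
Rumboldt2006,ADC_ROI_mean,pilocytic_astrocytoma,I,14,0.00144,0.00025
Rumboldt2006,ADC_ROI_mean,medulloblastoma,IV,12,0.00070,0.00012
Rumboldt2006,ADC_ROI_mean,ependymoma,II,6,0.00109,0.00020
DangouloffRos2016,nCBF_ROI_max,pilocytic_astrocytoma,I,50,0.92,0.41
DangouloffRos2016,nCBF_ROI_max,medulloblastoma,IV,40,1.88,0.69
DangouloffRos2016,nCBF_ROI_max,anaplastic_ependymoma,III,25,1.68,0.61
DangouloffRos2016,nCBF_ROI_max,diffuse_midline_glioma,IV,14,1.04,0.36
DangouloffRos2015,nCBF_ROI_max,pilocytic_astrocytoma,I,7,0.87,0.38
DangouloffRos2015,nCBF_ROI_max,medulloblastoma,IV,6,1.95,0.72
Kikuchi2017,nCBF_ROI_max,medulloblastoma,IV,10,1.92,0.70
Kikuchi2017,nCBF_ROI_max,glioblastoma,IV,9,2.38,0.81
Morana2018,nCBF_ROI_max,pilocytic_astrocytoma,I,15,0.95,0.42
Morana2018,nCBF_ROI_max,diffuse_midline_glioma,IV,10,1.08,0.37
Morana2018,nCBF_ROI_max,glioblastoma,IV,12,2.45,0.83
Yeom2014,nCBF_ROI_max,pilocytic_astrocytoma,I,20,0.89,0.40
Yeom2014,nCBF_ROI_max,medulloblastoma,IV,20,1.85,0.68
Yeom2014,nCBF_ROI_max,anaplastic_ependymoma,III,14,1.72,0.62
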