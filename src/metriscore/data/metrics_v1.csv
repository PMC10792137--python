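item_id,category_id,category_name,item_name,weight,condition
1,1,Study design,Adherence to radiomics and/or machine learning-specific checklists or guidelines,0.0368,always
2,1,Study design,Eligibility criteria that describe a representative study population,0.0735,always
3,1,Study design,High-quality reference standard with a clear definition,0.0919,always
4,2,Imaging data,Multi-center,0.0438,always
5,2,Imaging data,Clinical translatability of the imaging data source for radiomics analysis,0.0292,always
6,2,Imaging data,Imaging protocol with acquisition parameters,0.0438,always
7,2,Imaging data,The interval between imaging used and reference standard,0.0292,always
8,3,Segmentation,Transparent description of segmentation methodology,0.0337,segmentation
9,3,Segmentation,Formal evaluation of fully automated segmentation,0.0225,automated_segmentation
10,3,Segmentation,Test set segmentation masks produced by a single reader or automated tool,0.0112,segmentation
11,4,Image processing and feature extraction,Appropriate use of image preprocessing techniques with transparent description,0.0622,always
12,4,Image processing and feature extraction,Use of standardized feature extraction software,0.0311,handcrafted
13,4,Image processing and feature extraction,"Transparent reporting of feature extraction parameters, otherwise providing a default configuration statement",0.0415,always
14,5,Feature processing,Removal of non-robust features,0.0200,tabular
15,5,Feature processing,Removal of redundant features,0.0200,tabular
16,5,Feature processing,Appropriateness of dimensionality compared to data size,0.0300,tabular
17,5,Feature processing,Robustness assessment of end-to-end deep learning pipelines,0.0200,end_to_end_dl
18,6,Preparation for modeling,Proper data partitioning process,0.0599,always
19,6,Preparation for modeling,Handling of confounding factors,0.0300,always
20,7,Metrics and comparison,Use of appropriate performance evaluation metrics for task,0.0352,always
21,7,Metrics and comparison,Consideration of uncertainty,0.0234,always
22,7,Metrics and comparison,Calibration assessment,0.0176,always
23,7,Metrics and comparison,Use of uni-parametric imaging or proof of its inferiority,0.0117,always
24,7,Metrics and comparison,Comparison with a non-radiomic approach or proof of added clinical value,0.0293,always
25,7,Metrics and comparison,Comparison with simple or classical statistical models,0.0176,always
26,8,Testing,Internal testing,0.0375,always
27,8,Testing,External testing,0.0749,always
28,9,Open science,Data availability,0.0075,always
29,9,Open science,Code availability,0.0075,always
30,9,Open science,Model availability,0.0075,always
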