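垂体 8000 organ
异位垂体 500 organ
鞍区 300 organ
蝶鞍 120 organ
海绵窦 200 organ
视交叉 150 organ
垂体柄 120 organ
腺瘤 6000 disease
垂体腺瘤 9000 disease
垂体微腺瘤 4000 disease
垂体大腺瘤 4000 disease
垂体巨大腺瘤 3000 disease
微腺瘤 1200 disease
大腺瘤 1200 disease
巨大腺瘤 1000 disease
ACTH垂体微腺瘤 800 disease
泌乳素瘤 400 disease
库欣病 350 disease
肢端肥大症 300 disease
高泌乳素血症 200 disease
垂体功能减退 250 disease
尿崩症 200 disease
垂体卒中 150 disease
空泡蝶鞍 100 disease
颅咽管瘤 150 disease
脑膜瘤 150 disease
拉克囊肿 80 disease
鞍区占位 200 disease
垂体增生 100 disease
甲状腺功能减退 150 disease
肾上腺皮质功能减退 120 disease
糖尿病 300 disease
高血压 300 disease
视力下降 200 disease
视野缺损 180 disease
头痛 250 disease
闭经 120 disease
泌乳 100 disease
微 300 other
大 300 other
巨大 600 other
复发 2000 modifier
复发性 800 modifier
再发 100 modifier
难治 150 modifier
难治性 300 modifier
侵袭 300 modifier
侵袭性 1500 modifier
拟诊 400 modifier
可能 300 modifier
疑诊 200 modifier
待查 150 modifier
残留 400 modifier
肿瘤残留 300 modifier
术后残留 300 modifier
部分切除 150 modifier
全切除 150 modifier
术后 500 other
肿瘤 1500 disease
无功能 2500 endocrine
无功能性 1200 endocrine
功能性 300 endocrine
ACTH 1500 medicine
GH 1200 medicine
PRL 800 medicine
TSH 700 medicine
FSH 300 medicine
LH 300 medicine
IGF-1 120 medicine
促肾上腺皮质激素 600 medicine
生长激素 900 medicine
泌乳素 600 medicine
催乳素 200 medicine
促甲状腺激素 400 medicine
促性腺激素 200 medicine
性激素 150 medicine
激素 400 medicine
皮质醇 200 medicine
分泌型 900 other
混合型 500 other
分泌 250 other
ACTH分泌型 900 endocrine
GH分泌型 900 endocrine
PRL分泌型 600 endocrine
TSH分泌型 400 endocrine
FSH分泌型 200 endocrine
LH分泌型 200 endocrine
ACTH型 300 endocrine
GH型 300 endocrine
PRL型 200 endocrine
TSH型 150 endocrine
促肾上腺皮质激素分泌型 500 endocrine
生长激素分泌型 700 endocrine
泌乳素分泌型 500 endocrine
促甲状腺激素分泌型 300 endocrine
促性腺激素分泌型 150 endocrine
GH/PRL混合型 250 endocrine
GH/TSH混合型 250 endocrine
ACTH/GH混合型 200 endocrine
FSH/LH混合型 150 endocrine
GH/PRL/TSH混合型 100 endocrine
Knosp 800 examination
Knosp分级 600 examination
分级 300 examination
级 200 other
左侧 600 other
右侧 600 other
双侧 200 other
磁共振 300 examination
MRI 300 examination
CT 200 examination
增强扫描 120 examination
鞍区磁共振 150 examination
病理 250 examination
免疫组化 150 examination
地塞米松抑制试验 100 examination
奥曲肽 200 drug
兰瑞肽 100 drug
溴隐亭 200 drug
卡麦角林 150 drug
氢化可的松 150 drug
左甲状腺素 120 drug
生长抑素 150 drug
多巴胺受体激动剂 100 drug
替莫唑胺 80 drug
经蝶窦手术 200 other
经鼻蝶入路 150 other
开颅手术 100 other
伽玛刀 120 other
放疗 150 other
化疗 100 other
手术切除 150 other
随访 100 other
入院 120 other
出院 120 other
诊断 200 other
患者 300 other
pituitary 2000 organ
thyroid 150 organ
adenoma 1800 disease
microadenoma 700 disease
macroadenoma 700 disease
prolactinoma 150 disease
acromegaly 100 disease
micro 250 other
macro 250 other
giant 400 other
nonfunctioning 600 endocrine
functioning 150 endocrine
recurrent 500 modifier
recurrence 120 modifier
invasive 450 modifier
aggressive 200 modifier
refractory 120 modifier
ectopic 120 modifier
suspected 150 modifier
probable 80 modifier
highly 100 other
secreting 300 other
hormone 300 medicine
growth 250 other
adrenocorticotropic 150 medicine
stimulating 120 other
prolactin 150 medicine
cortisol 100 medicine
mixed 100 other
grade 200 examination
resection 150 other
incomplete 100 other
residual 100 other
tumor 200 disease
sellar 100 organ
cavernous 80 organ
sinus 80 organ
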