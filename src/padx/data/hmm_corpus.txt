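患者 因 头痛 伴 视力 下降 一 月 入院
查体 见 双侧 视野 缺损 明显
鞍区 磁共振 提示 垂体 占位 病变
肿瘤 向 鞍上 生长 压迫 视交叉
血清 泌乳素 水平 明显 升高
生长激素 与 胰岛素 样 生长 因子 升高
皮质醇 节律 消失 考虑 库欣病
行 经鼻 蝶窦 入路 肿瘤 切除 手术
术中 见 肿瘤 质地 软 血供 丰富
肿瘤 包绕 左侧 海绵窦 内 颈内动脉
术后 病理 证实 为 垂体 腺瘤
免疫组化 示 激素 染色 阴性
患者 术后 出现 一过性 尿崩症
给予 氢化可的松 替代 治疗
复查 磁共振 示 肿瘤 残留
残留 肿瘤 位于 海绵窦 内
建议 行 伽玛刀 放射 治疗
随访 期间 激素 水平 恢复 正常
视力 视野 较 术前 明显 改善
一 年 后 肿瘤 复发 再次 入院
复发 肿瘤 侵袭 周围 结构
给予 替莫唑胺 化疗 控制 病情
患者 闭经 泌乳 两 年 余
口服 溴隐亭 后 泌乳素 下降
肿瘤 体积 较 前 缩小
甲状腺 功能 与 性腺 功能 正常
肾上腺 皮质 功能 减退 需 替代
术前 评估 垂体 前叶 功能
动态 增强 扫描 见 微小 强化 灶
蝶鞍 扩大 鞍底 下陷
肿瘤 质地 韧 分块 切除
术后 恢复 顺利 如期 出院
出院 诊断 为 无功能 垂体 大 腺瘤
门诊 随访 复查 激素 全套
必要 时 行 地塞米松 抑制 试验
患者 肢端 肥大 面容 典型
手足 增大 皮肤 粗糙 多汗
血压 血糖 控制 欠佳
垂体 卒中 急诊 手术 减压
病理 回报 稀疏 颗粒 型 生长激素 腺瘤
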